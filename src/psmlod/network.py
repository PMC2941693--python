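"""Peak-intensity prediction: an 8-8-1 sigmoidal network and its
wrap-around permutation null.

The network predicts the log of the observed peak intensity (spectrum
normalized so the largest peak is 100) from eight fragment attributes.
Its peptide-level contribution is a Z score of the observed/predicted
intensity dot product against cyclic rotations of the predicted vector,
added to the metric-4 Z score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .chem import DEFAULT_TABLE, AminoAcidTable, TheoreticalIon

__all__ = [
    "ION_TYPE_CODE",
    "encode_features",
    "IntensityNetwork",
    "train_network",
    "wraparound_rotations",
    "intensity_z_score",
]

#: Ion-type input coding: no fragmentation, iminium, y, a, b.
ION_TYPE_CODE = {"precursor": 0, "iminium": 1, "y": 2, "a": 3, "b": 4}

N_FEATURES = 8
N_HIDDEN = 8

MIN_MATCHES_FOR_Z = 3
NULL_SD_FLOOR = 1e-9


def encode_features(
    ion: TheoreticalIon,
    peptide_sequence: str,
    parent_charge: int,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> np.ndarray:
    """Eight-feature vector for one fragment.

    1. ion type code (0..4)            5. fragment length / parent length
    2. parent charge                   6. H+K+R in fragment / H+K+R in parent
    3. fragment charge                 7. residue code, N-term side of the cut
    4. parent peptide length           8. residue code, C-term side of the cut

    Residue codes are the 20 evenly spaced hydrophobicity ranks on [0, 1].
    A parent without H/K/R gives ratio 0; ions without a fragmentation site
    (iminium, precursor) use their own residue (or the terminal residues)
    as the flanking identities.
    """
    n = len(peptide_sequence)
    frag = ion.fragment_sequence
    hkr = lambda s: sum(1 for ch in s if ch in "HKR")
    parent_hkr = hkr(peptide_sequence)
    hkr_ratio = hkr(frag) / parent_hkr if parent_hkr else 0.0

    if ion.ion_type == "y" and ion.index is not None:
        cut = n - ion.index  # site between cut and cut+1 (1-based residues)
        nterm, cterm = peptide_sequence[cut - 1], peptide_sequence[cut]
    elif ion.ion_type in ("b", "a") and ion.index is not None:
        cut = ion.index
        nterm, cterm = peptide_sequence[cut - 1], peptide_sequence[cut]
    elif ion.ion_type == "iminium":
        nterm = cterm = frag
    else:  # precursor: no fragmentation event
        nterm, cterm = peptide_sequence[0], peptide_sequence[-1]

    rank = table.hydrophobicity_rank
    return np.array(
        [
            float(ION_TYPE_CODE[ion.ion_type]),
            float(parent_charge),
            float(ion.charge),
            float(n),
            len(frag) / n,
            hkr_ratio,
            rank[nterm],
            rank[cterm],
        ]
    )


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    i = 0
    w1 = theta[i:i + N_FEATURES * N_HIDDEN].reshape(N_FEATURES, N_HIDDEN); i += N_FEATURES * N_HIDDEN
    b1 = theta[i:i + N_HIDDEN]; i += N_HIDDEN
    w2 = theta[i:i + N_HIDDEN]; i += N_HIDDEN
    b2 = float(theta[i])
    return w1, b1, w2, b2


@dataclass
class IntensityNetwork:
    """8-8-1 perceptron: sigmoid hidden layer, linear output.

    Inputs are standardized with the training-set mean/std stored on the
    model so that prediction is self-contained and deterministic.
    """

    theta: np.ndarray
    input_mean: np.ndarray
    input_std: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Xs = (X - self.input_mean) / self.input_std
        w1, b1, w2, b2 = _unpack(self.theta)
        hidden = 1.0 / (1.0 + np.exp(-(Xs @ w1 + b1)))
        return hidden @ w2 + b2

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
            "loss_trace": list(self.loss_trace),
            "epochs": self.epochs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "IntensityNetwork":
        return cls(
            theta=np.array(obj["theta"]),
            input_mean=np.array(obj["input_mean"]),
            input_std=np.array(obj["input_std"]),
            loss_trace=list(obj.get("loss_trace", [])),
            epochs=int(obj.get("epochs", 0)),
            seed=int(obj.get("seed", 0)),
        )


def _loss_and_grad(theta: np.ndarray, Xs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    w1, b1, w2, b2 = _unpack(theta)
    z1 = Xs @ w1 + b1
    h = 1.0 / (1.0 + np.exp(-z1))
    pred = h @ w2 + b2
    resid = pred - y
    n = y.size
    loss = float(resid @ resid) / n

    d_pred = 2.0 * resid / n
    g_w2 = h.T @ d_pred
    g_b2 = float(d_pred.sum())
    d_h = np.outer(d_pred, w2) * h * (1.0 - h)
    g_w1 = Xs.T @ d_h
    g_b1 = d_h.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]])
    return loss, grad


def train_network(
    features: np.ndarray,
    log_intensities: np.ndarray,
    epochs: int = 20,
    seed: int = 0,
) -> IntensityNetwork:
    """Fit the network by full-batch quasi-Newton (BFGS) minimization of the
    mean squared error on log-intensity targets.

    One "epoch" is one full-batch BFGS iteration; the recorded loss trace
    is non-increasing because the line search enforces descent.  Training
    is deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(log_intensities, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must be (n, {N_FEATURES})")
    if X.shape[0] != y.size:
        raise ValueError("feature/target length mismatch")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-9] = 1.0
    Xs = (X - mean) / std

    rng = np.random.default_rng(seed)
    n_params = N_FEATURES * N_HIDDEN + N_HIDDEN + N_HIDDEN + 1
    theta0 = rng.normal(0.0, 0.5, size=n_params)
    # small output weights + bias at the target mean: the initial predictor
    # is near-constant, which speeds convergence for flat or gentle targets
    theta0[N_FEATURES * N_HIDDEN + N_HIDDEN:] *= 0.1
    theta0[-1] = float(y.mean())

    trace = [_loss_and_grad(theta0, Xs, y)[0]]

    def callback(theta):
        trace.append(_loss_and_grad(theta, Xs, y)[0])

    result = minimize(
        _loss_and_grad,
        theta0,
        args=(Xs, y),
        jac=True,
        method="BFGS",
        callback=callback,
        options={"maxiter": epochs, "gtol": 1e-12},
    )
    return IntensityNetwork(
        theta=result.x,
        input_mean=mean,
        input_std=std,
        loss_trace=trace,
        epochs=epochs,
        seed=seed,
    )


def wraparound_rotations(values) -> list[list[float]]:
    """All non-identity cyclic rotations of an ordered intensity list.

    Each rotation reassigns every intensity to the previous position with
    wrap-around, preserving the intensity multiset; the identity alignment
    is excluded.  A length-1 list has no rotations.
    """
    vals = list(values)
    n = len(vals)
    if n < 1:
        raise ValueError("need at least one value")
    return [vals[shift:] + vals[:shift] for shift in range(1, n)]


def intensity_z_score(
    observed,
    predicted,
    min_matches: int = MIN_MATCHES_FOR_Z,
    sd_floor: float = NULL_SD_FLOOR,
) -> float:
    """Z score of the observed/predicted intensity dot product against the
    wrap-around rotation null.

    Both vectors are normalized to sum to 100 before the inner product.
    With fewer than ``min_matches`` matched fragments the metric abstains
    and contributes 0.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if obs.size < min_matches:
        return 0.0
    if obs.sum() <= 0 or pred.sum() <= 0:
        return 0.0
    obs = obs * (100.0 / obs.sum())
    pred = pred * (100.0 / pred.sum())
    true_dot = float(obs @ pred)
    null_dots = np.array([float(obs @ np.asarray(rot)) for rot in wraparound_rotations(pred)])
    sd = float(null_dots.std(ddof=1)) if null_dots.size > 1 else 0.0
    if sd < sd_floor:
        return 0.0
    return (true_dot - float(null_dots.mean())) / sd
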