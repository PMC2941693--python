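# psmlod

A framework for developing, validating, and comparing peptide–spectrum match
(PSM) scoring metrics. It digests a FASTA proteome into a mass-ordered
peptide index, selects candidates for DTA spectra by precursor mass, y-ion
hits, and a preliminary intensity-proportion score, then scores them with
log-odds (LOD) metrics of increasing sophistication:

1. **Metric 1** — fixed correct-match probability 0.5 against a
   uniform-random peak model (`ln(0.5 / (2·|error|·density))`).
2. **Metric 2** — the fixed probability replaced by empirically measured
   match proportions in 200 Da fragment-mass bins, per parent-charge class
   (3+ parents use the constant average of the 1+ and 2+ proportions).
3. **Metric 3** — both the correct and the random match probabilities
   taken from mass-binned tables, normalized to sum to one.
4. **Metric 4** — metric 3 weighted by a Gaussian model of the signed
   fragment mass error (mean and SD per 100 Da bin), capturing
   instrument-specific mass drift.
5. **nn4** — metric 4 plus a peptide-level Z score from an 8-8-1 sigmoidal
   neural network that predicts fragment peak intensities; the
   observed/predicted intensity dot product is calibrated against a
   wrap-around rotation null.

Peptide LODs are calibrated into Z scores against decoy candidates drawn
from a reversed-protein database in the same precursor-mass window. A
fragmentation explorer computes isoelectric points of complementary y/b
fragments at sites where only one of the pair was detected, and a synthetic
data module generates proteomes and DTA spectra with known ground truth
(per-mass-bin match probabilities, mass-error drift, a deterministic
intensity model, and uniform noise peaks) so the whole pipeline is testable
offline.

## Command line

```sh
# digest a proteome (and its reversed decoy) into peptide indexes
psmlod digest proteome.fasta -o target.index
psmlod digest proteome.fasta -o decoy.index --decoy

# score a directory of DTA spectra
psmlod score spectra/ --index target.index --decoy-index decoy.index \
    --metric 1 -o report.txt --summary summary.tsv

# build the empirical tables for metrics 2-4 from a metric-1 run
psmlod build-tables spectra/ --index target.index --decoy-index decoy.index \
    -o model.json

# rescore with a data-driven metric
psmlod score spectra/ --index target.index --decoy-index decoy.index \
    --metric 4 --model model.json -o report4.txt

# train the intensity network and attach it to the model
psmlod train-nn spectra/ --index target.index --decoy-index decoy.index \
    --model model.json -o model_nn.json

# complementary y/b isoelectric-point table
psmlod explore spectra/ --index target.index --decoy-index decoy.index \
    -o pairs.tsv

# synthetic data with a truth manifest
psmlod simulate sim.cfg -o simulated/ --n-spectra 200
```

Every subcommand also accepts `--config FILE` pointing at a flat
`key = value` file mirroring the scoring parameters
(`precursor_tol_da`, `fragment_tol_da`, `min_y_hits`, `min_prelim_score`,
`metric`, `min_decoys`, ...); explicit CLI flags override config values.
The default minimum preliminary score is 0.05 (0.30 can suit MALDI data);
the default Z acceptance threshold is 3.29.

Reports are plain text, one block per identification: fragments ranked by
intensity with observed (`obsMZ`) and expected (`expMZ`) m/z, per-fragment
LODs, the peptide LOD (the sum of the fragment LODs), and the decoy Z
score. Dots in the `seq` line delimit flanking residues not part of the
peptide. `--summary` adds a one-row-per-spectrum TSV for scripting.

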