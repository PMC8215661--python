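# alpzone

Analysis pipeline for soil eDNA metabarcoding of green algae (*Chlorophyta*)
along Alpine elevational gradients — the post-sequencing half of a
metabarcoding survey, from the annotated MOTU × PCR read-count table to niche
inference, rebuilt as a tested Python library with numbered analysis drivers.

It is written for molecular ecologists who have OBITools-style MOTU tables
(with PCR replicates, extraction/PCR blanks and mock-community positive
controls) and want a reproducible, scriptable version of the standard
analysis chain:

1. **Quality control** (`alpzone.qc`) — amplicon length bounds, rare-variant
   removal (peak ≤ 10 reads), target-clade restriction, removal of MOTUs more
   abundant in negative controls than in any sample, rejection of failed PCRs
   (< 200 reads for Chlo01/Chlo02, < 1,000 for Euka03), Hellinger-distance
   replicate-outlier flagging, and aggregation to a sample × MOTU
   relative-frequency matrix.
2. **Diversity** (`alpzone.diversity`) — Hill numbers
   ^qD = (Σ pᵢ^q)^{1/(1−q)} with q = 1 (exp of Shannon entropy) as the working
   order; β = γ/α partitioning; seven-slice gradient ANOVA R² with
   Kruskal–Wallis tests and Benjamini–Hochberg adjustment; Mann–Whitney group
   contrasts; endemism profiles.
3. **Ordination** (`alpzone.ordination`) — iterative VIF = 1/(1−R²) variable
   selection (threshold 5), PCoA of Euclidean-on-Hellinger distances,
   Site-conditioned partial RDA with 999-permutation tests, forward-backward
   selection, variance partitioning by adjusted-R² differences, and
   Tukey-bisquare IRLS regression for cross-marker comparisons.
4. **Niche inference** (`alpzone.niche`) — Outlying Mean Index decomposition
   (marginality, marginal tolerance, residual tolerance), the dual permutation
   criterion for specialization (marginality larger *or* marginal tolerance
   smaller than expected, 999 permutations), abundance-weighted optimal ranges
   along each gradient, and the PCA of specialized taxa's niche centres.
5. **Synthetic study** (`alpzone.synthetic`) — a generator that emulates the
   field design (5 sites tiling 1,250–2,940 m in 200 m steps, two soil
   horizons, PCR triplicates, blanks, a 13-species halving-dilution mock
   community, spiked contaminants, forced PCR failures, niche-structured taxa
   of two dominant classes) and exposes the ground truth, so every stage is
   testable without any sequencing download.

See `docs/methods.md` for the models, assumptions, parameter defaults and
known limitations.

## Worked example

The numbered drivers run the whole study on synthetic data (outputs under
`results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_qc.py
python analysis/03_diversity.py
python analysis/04_ordination.py --seed 1
python analysis/05_niche.py --seed 1
```

With seed 1 this prints, among other things:

```
table: 76 MOTUs x 198 PCRs, 3,510,712 reads -> results/data
contaminant recovery: removed set == spiked set: True
forced low-depth PCRs all rejected: True (9 forced, 21 rejected in total)
theoretical mock-community ^1D = 4.00 (rounds to 4.0)
mean per-PCR ^1D = 14.91 (sd 3.32, 171 PCRs)
gamma = 25.28, alpha = 14.91, beta = gamma/alpha = 1.70
VIF screen kept ['Elevation', 'pH', 'Nitrogen', 'C_N_ratio', 'OrganicMatter',
                 'FDD', 'CWD', 'DTR']; removed Carbon (VIF 9.6)
stepwise selection retained: ['Elevation', 'pH']
partial RDA: constrained R2 = 0.483, adjusted R2 = 0.465, permutation p = 0.001
31/51 taxa specialized (dual criterion, 999 permutations)
vs ground truth: specialist sensitivity = 0.91, generalist flag rate = 0.06
```

Reading the numbers: the QC chain recovers exactly the contaminants and
failed PCRs the generator planted; the 13-species halving mock community has
the analytic diversity ¹D = 4.0 (exp(2 ln 2) in the infinite-series limit);
per-PCR diversity averages ~15 effective taxa while the pooled gradient holds
~25, i.e. β ≈ 1.7 effective communities; collinearity screening drops Carbon
(VIF 9.6 > 5); the Site-conditioned RDA attributes most explained turnover to
Elevation; and the dual OMI criterion flags 91% of the true specialists while
touching only 6% of the flat-response generalists.

The same stages are available as a CLI for real tables
(`alpzone simulate|qc|diversity|ordinate|niche`, see `--help`); every command
is byte-deterministic under a fixed `--seed`.

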