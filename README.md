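# xsilence

Allele-specific analysis of Xist-mediated X-chromosome inactivation (XCI).

In XX cells carrying a doxycycline-inducible *Xist* allele on an
interspecific (SNP-rich) background, chromatin-associated RNA-seq fragments
can be assigned to the inactive (Xi) or active (Xa) X allele. This package
implements the downstream quantitative analysis of such experiments, for
researchers studying gene silencing dynamics during XCI:

* **Allelic quantification** — per-gene allelic ratio Xi/(Xi+Xa), gene
  admission filters (≥10 allelically assigned fragments in >80% of
  wild-type samples; baseline mESC ratio strictly inside 0.1–0.9),
  replicate averaging, RPM/TPM normalization and expression tertiles.
* **Silencing kinetics** — each gene's trajectory over days of induction
  and differentiation is fit with the exponential decay model

      y(t) = yf + y0·e^(−tk)

  where y is the allelic ratio, y0+yf the initial ratio, yf the plateau
  (fixed at 0 except for escapees, defined by allelic ratio > 0.1 in
  mature differentiated cells) and k the silencing rate per day. The
  silencing half-time is the time the curve reaches F·(y0+yf) with F = 0.5:

      t½ = −(1/k)·ln((F·(y0+yf) − yf) / y0)     (ln 2 / k when yf = 0)

  Half-times define fast/intermediate/slow kinetic classes (rank tertiles).
* **Pathway-dependence classification** — SmcHD1-dependence
  (dependent / partial / not / escapee, from wild-type vs knockout mature
  Xi ratios) and SPEN-SPOC dependence (from the day-6 Dox−NoDox change in
  SPOC-mutant cells), with exact Wilcoxon rank-sum and Fisher tests for
  group comparisons (full enumeration at small n, mid-rank ties).
* **Spike-calibrated allelic ChIP** — fixed 250-kb windows over the
  allelically analysable 103.5-Mb chrX region (414 windows), occupancy-ratio
  spike-in calibration, per-allele IP/input enrichment, Xi−Xa and Xi/Xa
  summaries, and window blacklisting (±2.5 MAD input outliers, lowest-5%
  allelic input).
* **Synthetic data with ground truth** — a generator emulating the allelic
  count structure of the assay (gamma-Poisson totals, SNP-dependent allelic
  thinning, beta-binomial Xi draws, escapees, mutant lines, planted ChIP
  enrichment and artifacts) so every stage is testable without external data.

## Worked example

`examples/02_silencing_kinetics.py` simulates a 300-gene time course
(days 0–7, duplicates, ~100 allelic fragments per gene and sample), fits
every gene and scores recovery against the generator's truth:

```
               y0   yf         k    t_half  escapee kinetic_class
gene_id
gene001  0.397144  0.0  0.252083  2.749682    False          slow
gene002  0.533854  0.0  0.653973  1.059901    False  intermediate
gene003  0.443040  0.0  0.345618  2.005529    False          slow

Spearman(true, estimated t_half) = 0.968  (n = 289)
escapee-flag accuracy           = 0.983
kinetic classes: {'slow': 97, 'intermediate': 97, 'fast': 97, 'unclassified': 9}
```

Each row is one gene's fitted decay: `gene001` has initial allelic ratio
≈0.40, silences at 0.25/day and takes ≈2.7 days to reach half its initial
ratio, placing it in the slow tertile. The Spearman correlation shows the
ranking of silencing speeds is recovered from noisy counts; nine genes with
flat or undefined trajectories stay unclassified. The other examples cover
allelic ratios and filters (01), dependence classification and group
statistics (03), and calibrated ChIP windows with blacklisting (04).

A thin CLI wraps the same stages:

```sh
xsilence simulate --config cfg.yaml --out sim/ --seed 1
xsilence silencing --config sil.yaml --out results/ --seed 1
xsilence chip --config chip.yaml --out chip_out/ --seed 1
```

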