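# dielomics

Why do cyanobacteria show strong day–night oscillations in transcription and
protein synthesis, yet nearly constant protein levels? `dielomics` packages
the quantitative machinery needed to study that question: a protein
mass-balance model with diurnal forcing, the read-counting rules that turn
mRNA-seq and ribosome-profiling alignments into per-gene abundances, an
ANOVA-based cyclic-gene detection and clustering pipeline for matched
transcriptome/translatome/proteome time courses, a turbidostat growth-rate
estimator, and a synthetic-data generator that emulates the whole experiment
with known ground truth.

It is aimed at systems biologists working on diurnal/circadian gene
expression in phototrophic microbes, and at anyone who needs a tested
reference implementation of these standard analysis steps.

## The model

For a protein J in a cell whose total protein concentration P_TOT is
constant, the fraction F_P,J of total protein made up by J obeys

```
dF_P,J/dt = F_S,J(t) · (μ(t) + k_D,MEAN) − F_P,J · (μ(t) + k_D,J(t))
```

where F_S,J is the fraction of bulk protein synthesis devoted to J, μ the
specific growth rate (h⁻¹), k_D,MEAN the bulk protein degradation rate and
k_D,J the gene-specific degradation rate. Constant P_TOT forces bulk
synthesis to equal bulk depletion, S_TOT = P_TOT·(μ + k_D,MEAN), which is
why the *bulk turnover* μ + k_D,MEAN appears as the synthesis gain.

With constant rates a = μ + k_D,MEAN, b = μ + k_D,J and a sinusoidal
synthesis fraction F_S = 1 + A·sin(ωt + φ), the periodic attractor is

```
F_P(t) = a/b + (aA/√(b²+ω²)) · sin(ωt + φ − atan2(ω, b))
```

so the peak-to-trough fold change ("relative amplitude") of the protein is
bounded by the synthesis fold change and shrinks as b falls below the
diurnal angular frequency ω = 2π/24 h⁻¹. Slow turnover alone therefore
flattens protein oscillations — no translational or degradational
regulation is required.

## Worked example

Simulate an "average" gene (k_D,J = k_D,MEAN) under the median-amplitude
synthesis forcing (3.05-fold, 24 h period), at the measured daily-average
growth rate μ = 0.018 h⁻¹ and a slow bulk degradation rate of 0.01 h⁻¹:

```python
from dielomics import ProteinTurnoverModel, TurnoverParams

trace = ProteinTurnoverModel(TurnoverParams(
    growth_rate=0.018,
    bulk_degradation_rate=0.01,
    gene_degradation_rate=0.01,
)).simulate()
print(trace.summary())
```

```
Protein turnover simulation
===========================
period                      24.00 h
horizon                    240.00 h
relative amplitude         1.1138 fold
absolute amplitude        0.10766
daily mean abundance      0.99999
phase lag                   5.590 h
converged to cycle           True
```

Although synthesis swings 3.05-fold, the protein moves only 1.11-fold and
lags synthesis by ~5.6 h. The whole scenario battery (slow/fast bulk
turnover, elevated gene-specific degradation, anticorrelated degradation,
fluctuating growth):

```python
from dielomics import run_scenarios
print(run_scenarios())
```

```
                              relative_amplitude  absolute_amplitude  daily_mean_abundance  phase_lag_h  converged
scenario
A_slow_turnover                         1.113781            0.107655              0.999990         5.59       True
A_fast_turnover                         1.525234            0.415989              1.000000         4.38       True
B_gene_specific                         1.525234            0.098709              0.237288         4.38       True
C_anticorrelated_degradation            3.073681            0.278438              0.260875         4.54       True
D_diurnal_growth                        1.091427            0.086605              0.978572         5.74      False
```

Raising bulk turnover to 0.118 h⁻¹ raises the amplitude to 1.53-fold via a
larger absolute amplitude; raising only the gene's own degradation gives the
same relative amplitude by lowering the daily mean instead.

The multi-omics pipeline runs the same way on real or synthetic tables:

```python
from dielomics import DiurnalExpressionModel, generate_triplet

trip = generate_triplet(seed=1)
results = DiurnalExpressionModel(
    trip.tables["mrna"], trip.tables["ribo"], trip.tables["protein"],
    trip.samples, trip.counts["mrna_counts"], trip.counts["ribo_counts"],
    timepoint_hours=trip.timepoint_hours,
).fit()
print(results.summary())
```

```
Diurnal multi-omics analysis
============================
genes analysed               965
cyclic genes                 306 (32%)
cluster silhouette (k)      0.96
median amplitude mrna       3.02-fold (log2 1.60)
median amplitude ribo       3.66-fold (log2 1.87)
median amplitude protein    1.42-fold (log2 0.50)
pooled r mrna-ribo           0.89
pooled r ribo-protein        0.06
pooled r mrna-protein        0.07
amplitude~turnover trend  r=-0.01, p=0.88
cluster sizes             G0:659, G1:95, G2:57, G3:85, G4:69
```

The
mRNA and ribosome levels oscillate ~3-fold and track each other, while the
protein level is nearly flat — the damping the turnover model predicts.

Everything is also reachable from the shell:

```
dielomics simulate --out out/
dielomics generate triplet --seed 1 --out data/
dielomics analyze --mrna data/mrna.tsv --ribo data/ribo.tsv \
    --protein data/protein.tsv --samples data/samples.tsv \
    --gene-counts data/gene_counts.tsv --out analysis/
dielomics growth --input trace.csv --out mu/
dielomics quantify --mode ribo --alignments reads.bed --genes genes.tsv --out quant/
```

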