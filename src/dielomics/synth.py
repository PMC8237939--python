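"""Synthetic multi-omics and bioreactor data with known ground truth.

The generator emulates the statistical structure of a diurnal multi-omics
experiment in a cyanobacterial turbidostat culture:

* five diurnal time points (1 h before/after sunrise, midday, 1 h
  before/after sunset) with two replicates each (three for one
  ribosome-profiling time point), ~10^3 genes;
* ~43% of genes cyclic, with sinusoid-like log2 mRNA profiles in four phase
  groups and a log-normal peak-to-trough amplitude (median 3-fold);
* translatome tracking the transcriptome up to a per-gene-and-time-point
  deviation (tuned so the pooled mRNA-ribosome correlation of cyclic-gene
  mean profiles is ~0.88);
* proteome produced by forward simulation of the protein mass-balance model
  per gene, sampled on the converged diurnal cycle, plus measurement noise;
* a turbidostat optical-density/feed log driven by a day-night growth-rate
  curve through a proportional feed controller;
* read alignments for the quantification rules.

Every output is reproducible from (config, seed) and passes the consuming
module's input validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .forcing import ForcingSpec, evaluate_forcing
from .growth import TurbidostatTrace
from .quantify import AlignmentRecord, GeneModel

__all__ = [
    "GeneratorConfig",
    "SyntheticTriplet",
    "generate_triplet",
    "generate_turbidostat",
    "generate_alignments",
]

TWO_PI = 2.0 * np.pi

#: diurnal sampling design: time-point id -> hours after sunrise (mod 24)
SAMPLE_TIMES = {1: 23.0, 2: 1.0, 3: 6.0, 4: 11.0, 5: 13.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic triplet generator."""

    n_genes: int = 1000
    cyclic_fraction: float = 0.43
    #: peak hours of the four phase groups (sunrise, midday, sunset, midnight)
    phase_groups: tuple = (0.0, 6.0, 12.0, 18.0)
    #: median peak-to-trough fold change of cyclic mRNA profiles
    amplitude_median_fold: float = 3.0
    #: log-normal dispersion (sigma of ln amplitude_log2)
    amplitude_dispersion: float = 0.35
    #: within-replicate noise, log2 units (mRNA and ribosome levels)
    replicate_noise_sd: float = 0.2
    #: gene x time-point deviation of the translatome from the transcriptome,
    #: log2 units; calibrated so pooled mRNA-ribo r of cyclic mean profiles
    #: is ~0.88 under the defaults
    tracking_noise_sd: float = 0.35
    #: protein measurement noise, log2 units
    protein_noise_sd: float = 0.3
    #: growth rate and bulk degradation rate of the turnover model (1/h)
    mu: float = 0.018
    kd_mean: float = 0.01
    #: per-gene degradation rates are log-normal around this median (1/h)
    kd_gene_median: float = 0.01
    kd_gene_dispersion: float = 0.5
    period: float = 24.0
    #: replicates per time point; the ribosome level gets one extra
    #: replicate at the time point 1 h after sunrise
    n_replicates: int = 2
    ribo_triplicate_timepoint: int = 2
    #: median mRNA baseline (abundance units) and log-normal ln-sigma
    baseline_median: float = 50.0
    baseline_dispersion: float = 1.5
    #: sequencing depth factors converting baselines to total read counts
    mrna_depth: float = 10.0
    ribo_depth: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cyclic_fraction <= 1.0):
            raise ValueError("cyclic_fraction must be in [0, 1]")
        for name in ("replicate_noise_sd", "tracking_noise_sd", "protein_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(not (0 <= p < self.period) for p in self.phase_groups):
            raise ValueError("phase group peaks must lie within [0, period)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per time point")


@dataclass
class SyntheticTriplet:
    """Generated abundance tables, sample sheet, counts and ground truth."""

    tables: dict[str, pd.DataFrame]
    samples: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig
    seed: int
    timepoint_hours: dict = field(default_factory=lambda: dict(SAMPLE_TIMES))

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for level, table in self.tables.items():
            table.to_csv(path / f"{level}.tsv", sep="\t")
        self.samples.to_csv(path / "samples.tsv", sep="\t", index=False)
        self.counts.to_csv(path / "gene_counts.tsv", sep="\t")
        self.truth.to_csv(path / "ground_truth.tsv", sep="\t")

    @staticmethod
    def read_tables(path):
        """Read triplet TSVs written by :meth:`to_dir` back into frames."""
        path = Path(path)
        tables = {
            level: pd.read_csv(path / f"{level}.tsv", sep="\t", index_col=0)
            for level in ("mrna", "ribo", "protein")
        }
        samples = pd.read_csv(path / "samples.tsv", sep="\t")
        counts = pd.read_csv(path / "gene_counts.tsv", sep="\t", index_col=0)
        return tables, samples, counts


def _log2_profile(amp_log2, peak_hour, t, period):
    """Centered sinusoid in log2 space with peak-to-trough ``amp_log2``."""
    omega = TWO_PI / period
    return (np.asarray(amp_log2) / 2.0) * np.cos(
        omega * (np.asarray(t) - np.asarray(peak_hour))
    )


def _simulate_proteome(
    amp_log2: np.ndarray,
    peak: np.ndarray,
    kd_gene: np.ndarray,
    config: GeneratorConfig,
    sample_hours: np.ndarray,
) -> np.ndarray:
    """Converged periodic protein abundance fractions, all genes at once.

    Integrates dF_P/dt = a * 2**s_g(t) - b_g * F_P for ten periods from the
    mean-forcing steady state, then evaluates the final cycle at the given
    hours (mod period). Returns an (n_genes, n_timepoints) array.
    """
    period = config.period
    a = config.mu + config.kd_mean
    b = config.mu + kd_gene
    half = amp_log2 / 2.0
    omega = TWO_PI / period

    def forcing(t):
        return np.exp2(half * np.cos(omega * (t - peak)))

    grid = np.linspace(0.0, period, 257)
    mean_fs = np.trapezoid(
        np.exp2(half[:, None] * np.cos(omega * (grid[None, :] - peak[:, None]))),
        grid,
        axis=1,
    ) / period
    y0 = a / b * mean_fs

    n_burn = 10
    t_end = n_burn * period
    t_eval = t_end - period + np.sort(np.mod(sample_hours, period))
    sol = solve_ivp(
        lambda t, y: a * forcing(t) - b * y,
        (0.0, t_end),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=1e-6,
        atol=1e-9,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"proteome forward simulation failed: {sol.message}")
    order = np.argsort(np.argsort(np.mod(sample_hours, period)))
    return sol.y[:, order]


def generate_triplet(
    config: GeneratorConfig | None = None, seed: int = 0
) -> SyntheticTriplet:
    """Generate one matched mRNA / ribosome / protein dataset.

    Cyclic genes get sinusoidal log2 mRNA profiles; the ribosome level adds
    a gene x time-point tracking deviation; the protein level is the
    forward-simulated converged abundance fraction of the turnover model.
    Replicate values add log-normal measurement noise on top.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    tp_ids = np.array(sorted(SAMPLE_TIMES))
    hours = np.array([SAMPLE_TIMES[t] for t in tp_ids])

    # --- ground truth ----------------------------------------------------
    n_cyclic = int(round(config.cyclic_fraction * n))
    cyclic = np.zeros(n, dtype=bool)
    cyclic[rng.permutation(n)[:n_cyclic]] = True
    group = np.where(
        cyclic, rng.integers(0, len(config.phase_groups), size=n), -1
    )
    peak = np.where(cyclic, np.asarray(config.phase_groups)[group], 0.0)
    amp = np.where(
        cyclic,
        np.exp(
            np.log(np.log2(config.amplitude_median_fold))
            + config.amplitude_dispersion * rng.standard_normal(n)
        ),
        0.0,
    )
    kd_gene = config.kd_gene_median * np.exp(
        config.kd_gene_dispersion * rng.standard_normal(n)
    )
    baseline = config.baseline_median * np.exp(
        config.baseline_dispersion * rng.standard_normal(n)
    )

    profile = _log2_profile(amp[:, None], peak[:, None], hours[None, :], config.period)
    tracking = rng.normal(0.0, config.tracking_noise_sd, size=(n, len(tp_ids)))
    proteome = _simulate_proteome(amp, peak, kd_gene, config, hours)

    # --- sample sheet ----------------------------------------------------
    rows = []
    for level in ("mrna", "ribo", "protein"):
        for tp in tp_ids:
            n_rep = config.n_replicates
            if level == "ribo" and tp == config.ribo_triplicate_timepoint:
                n_rep += 1
            for rep in range(1, n_rep + 1):
                rows.append(
                    {
                        "sample_id": f"{level}_t{tp}_r{rep}",
                        "level": level,
                        "time_point": int(tp),
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(rows)

    # --- abundance tables -------------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    for level in ("mrna", "ribo", "protein"):
        meta = samples[samples["level"] == level]
        data = {}
        for _, row in meta.iterrows():
            tp_idx = int(np.searchsorted(tp_ids, row["time_point"]))
            if level == "mrna":
                log2_true = profile[:, tp_idx]
                base, noise_sd = baseline, config.replicate_noise_sd
            elif level == "ribo":
                log2_true = profile[:, tp_idx] + tracking[:, tp_idx]
                base, noise_sd = baseline, config.replicate_noise_sd
            else:
                log2_true = np.log2(proteome[:, tp_idx])
                base, noise_sd = baseline, config.protein_noise_sd
            noise = rng.normal(0.0, noise_sd, size=n)
            data[row["sample_id"]] = base * np.exp2(log2_true + noise)
        tables[level] = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))

    # --- per-gene total read counts for the count filters -----------------
    counts = pd.DataFrame(
        {
            "mrna_counts": np.round(baseline * config.mrna_depth).astype(int),
            "ribo_counts": np.round(baseline * config.ribo_depth).astype(int),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    observed_amp = profile.max(axis=1) - profile.min(axis=1)
    truth = pd.DataFrame(
        {
            "cyclic": cyclic,
            "phase_group": group,
            "peak_hour": np.where(cyclic, peak, np.nan),
            "amp_log2": amp,
            "observed_amp_log2": observed_amp,
            "kd_gene": kd_gene,
            "baseline": baseline,
            "protein_daily_mean_fraction": proteome.mean(axis=1),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticTriplet(
        tables=tables,
        samples=samples,
        counts=counts,
        truth=truth,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# turbidostat
# ---------------------------------------------------------------------------


def generate_turbidostat(
    mu_forcing: ForcingSpec | None = None,
    setpoint_od: float = 0.725,
    controller_gain: float = 2.0,
    noise_sd: float = 0.01,
    duration_h: float = 48.0,
    dt_s: float = 30.0,
    volume_l: float = 1.6,
    seed: int = 0,
) -> tuple[TurbidostatTrace, pd.DataFrame]:
    """Simulate a turbidostat log under a day-night growth-rate curve.

    A proportional feed controller holds the optical density at the set
    point: D = gain * (OD_obs / setpoint - 1), clipped at zero. The observed
    OD carries multiplicative Gaussian noise; the controller acts on the
    noisy reading, as a real bioreactor does. Returns the trace and a
    ground-truth frame (time_h, mu_true).
    """
    if mu_forcing is None:
        mu_forcing = ForcingSpec.day_night(amplitude=0.05)
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    rng = np.random.default_rng(seed)
    dt_h = dt_s / 3600.0
    n = int(round(duration_h / dt_h)) + 1
    time = np.arange(n) * dt_h
    mu_true = evaluate_forcing(mu_forcing, time)

    od_true = np.empty(n)
    od_obs = np.empty(n)
    feed = np.empty(n)
    od = setpoint_od
    eps = rng.normal(0.0, noise_sd, size=n)
    for i in range(n):
        od_true[i] = od
        od_obs[i] = od * (1.0 + eps[i])
        dilution = max(0.0, controller_gain * (od_obs[i] / setpoint_od - 1.0))
        feed[i] = dilution * volume_l
        od = od * (1.0 + (mu_true[i] - dilution) * dt_h)
        if not (0.05 * setpoint_od < od < 20.0 * setpoint_od):
            raise RuntimeError("turbidostat controller diverged")
    trace = TurbidostatTrace(
        time=time, od=np.maximum(od_obs, 1e-6), feed_rate=feed, volume=volume_l
    )
    truth = pd.DataFrame({"time_h": time, "mu_true": mu_true})
    return trace, truth


# ---------------------------------------------------------------------------
# read alignments
# ---------------------------------------------------------------------------


def generate_alignments(
    genes: list[GeneModel],
    expression_weights: np.ndarray,
    n_reads: int,
    read_lengths: dict[int, float] | None = None,
    dataset: str = "mrna",
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Place reads uniformly within their gene's CDS, strand-matched.

    Read counts per gene are multinomial with the given expression weights;
    read lengths are drawn from ``read_lengths`` (length -> probability).
    Genes shorter than a drawn read are skipped with a warning.
    """
    weights = np.asarray(expression_weights, dtype=float)
    if len(weights) != len(genes):
        raise ValueError("one expression weight per gene required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("expression weights must be >= 0 with positive sum")
    if read_lengths is None:
        read_lengths = {30: 0.5, 28: 0.3, 32: 0.2} if dataset == "ribo" else {60: 1.0}
    rng = np.random.default_rng(seed)
    lengths = np.array(sorted(read_lengths))
    probs = np.array([read_lengths[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()

    per_gene = rng.multinomial(n_reads, weights / weights.sum())
    records: list[AlignmentRecord] = []
    n_skipped = 0
    for gene, count in zip(genes, per_gene):
        if count == 0:
            continue
        read_lens = lengths[rng.choice(len(lengths), size=count, p=probs)]
        for length in read_lens:
            if gene.length < length:
                n_skipped += 1
                continue
            start = int(
                rng.integers(gene.cds_start, gene.cds_end - int(length) + 1)
            )
            records.append(
                AlignmentRecord(
                    reference=gene.reference,
                    start=start,
                    end=start + int(length),
                    strand=gene.strand,
                    dataset=dataset,
                )
            )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} read(s) longer than their gene", stacklevel=2
        )
    return records


def write_alignments_bed(records, path) -> None:
    """Write alignment records as a BED6-like TSV."""
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            fh.write(
                f"{rec.reference}\t{rec.start}\t{rec.end}\tread{i}"
                f"\t{rec.read_length}\t{rec.strand}\n"
            )
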