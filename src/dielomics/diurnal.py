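"""Integrated diurnal analysis of mRNA, ribosome-footprint and protein data.

The pipeline takes matched gene x sample abundance tables at three omics
levels across five diurnal time points (two-three replicates each) and

1. filters genes: minimum read counts (mRNA >= 30, ribosome >= 60), removes
   proteins whose per-time-point log2 intensity SD exceeds 1 anywhere, and
   keeps only genes with >= 2 replicate values at every time point in every
   level;
2. log2-transforms and centers each gene around its daily average;
3. calls "cyclic" genes on the mRNA level with one-way ANOVA across time
   points, Benjamini-Hochberg correction (q < 0.1) and a maximum absolute
   log2 fold change > 1 between time-point means;
4. clusters cyclic mRNA profiles hierarchically (Pearson-correlation
   distance, Ward linkage) into G1-G4 ordered by peak time, with an average
   silhouette width diagnostic; non-cyclic genes form G0;
5. computes per-gene peak-to-peak relative amplitudes at each level, pooled
   cross-level correlations, and the trend of protein amplitude against a
   gene-specific turnover proxy (daily-mean ribosome / protein abundance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiurnalExpressionModel",
    "DiurnalExpressionResults",
    "filter_genes",
    "log2_center",
    "call_cyclic",
    "cluster_cyclic",
    "relative_amplitude",
    "cross_level_correlation",
    "turnover_trend",
]

LEVELS = ("mrna", "ribo", "protein")


def _check_samples(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "level", "time_point", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return samples


def _level_meta(samples: pd.DataFrame, level: str) -> pd.DataFrame:
    meta = samples[samples["level"] == level]
    if meta.empty:
        raise ValueError(f"no samples for level {level!r}")
    return meta


# ---------------------------------------------------------------------------
# filtering and transformation
# ---------------------------------------------------------------------------


def filter_genes(
    tables: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    mrna_total_counts: pd.Series | None = None,
    ribo_total_counts: pd.Series | None = None,
    min_mrna_reads: float = 30,
    min_ribo_reads: float = 60,
    max_protein_log2_sd: float = 1.0,
    min_replicates: int = 2,
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the gene-retention filter cascade.

    Returns (retained gene index, attrition table with one row per filter).
    Raises ``ValueError`` with the attrition report embedded if nothing
    survives.
    """
    samples = _check_samples(samples)
    genes = tables["mrna"].index
    for level in LEVELS:
        genes = genes.intersection(tables[level].index)
    attrition = []
    keep = pd.Series(True, index=genes)

    if mrna_total_counts is not None:
        bad = mrna_total_counts.reindex(genes).fillna(0) < min_mrna_reads
        attrition.append(("mrna_min_reads", int(bad.sum())))
        keep &= ~bad
    if ribo_total_counts is not None:
        bad = ribo_total_counts.reindex(genes).fillna(0) < min_ribo_reads
        attrition.append(("ribo_min_reads", int(bad.sum())))
        keep &= ~bad

    # protein precision filter: per-time-point log2 SD > threshold at ANY tp
    prot_meta = _level_meta(samples, "protein")
    prot = tables["protein"].loc[genes, prot_meta["sample_id"]]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_prot = np.log2(prot.where(prot > 0))
    sd_bad = pd.Series(False, index=genes)
    for _, group in prot_meta.groupby("time_point"):
        sds = log2_prot[group["sample_id"]].std(axis=1, ddof=1)
        sd_bad |= sds > max_protein_log2_sd
    attrition.append(("protein_log2_sd", int((sd_bad & keep).sum())))
    keep &= ~sd_bad

    # >= min_replicates non-missing positive values per time point per level
    rep_bad = pd.Series(False, index=genes)
    for level in LEVELS:
        meta = _level_meta(samples, level)
        values = tables[level].loc[genes, meta["sample_id"]]
        for _, group in meta.groupby("time_point"):
            n_ok = (values[group["sample_id"]] > 0).sum(axis=1)
            rep_bad |= n_ok < min_replicates
    attrition.append(("min_replicates", int((rep_bad & keep).sum())))
    keep &= ~rep_bad

    report = pd.DataFrame(attrition, columns=["filter", "n_removed"])
    retained = genes[keep]
    if len(retained) == 0:
        raise ValueError(f"no genes survive filtering; attrition:\n{report}")
    return retained, report


def log2_center(values: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and center each gene on its daily average.

    Every row of the output has mean zero; a nonpositive input value is an
    error (zeros should have been removed by the count filters upstream).
    """
    arr = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        bad = values.index[np.where((~np.isfinite(arr)) | (arr <= 0))[0]]
        raise ValueError(f"nonpositive abundance for gene(s): {list(bad[:5])}")
    log2 = np.log2(arr)
    centered = log2 - log2.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=values.index, columns=values.columns)


def timepoint_means(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per time point (arithmetic in the given space)."""
    cols = {}
    for tp, group in meta.groupby("time_point"):
        cols[tp] = values[group["sample_id"]].mean(axis=1)
    return pd.DataFrame(cols).sort_index(axis=1)


# ---------------------------------------------------------------------------
# cyclic-gene calling
# ---------------------------------------------------------------------------


def _anova_sums_of_squares(values: pd.DataFrame, meta: pd.DataFrame):
    """Vectorized one-way ANOVA across time points, per gene (row).

    Returns (F, p, ssb, ssw, df_between, df_within).
    """
    groups = [g["sample_id"].tolist() for _, g in meta.groupby("time_point")]
    k = len(groups)
    x = values.to_numpy(dtype=float)
    n_total = sum(len(g) for g in groups)
    grand = x.mean(axis=1)
    ssb = np.zeros(len(values))
    ssw = np.zeros(len(values))
    for cols in groups:
        sub = values[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        ssb += len(cols) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(F, df_b, df_w)
    # degenerate convention: zero within-group variance -> p 0 if the means
    # differ at all, 1 if every value is identical
    zero_ssw = ssw <= 0
    p = np.where(zero_ssw & (ssb > 0), 0.0, p)
    p = np.where(zero_ssw & (ssb <= 0), 1.0, p)
    return F, p, ssb, ssw, df_b, df_w


def call_cyclic(
    centered: pd.DataFrame,
    meta: pd.DataFrame,
    q_threshold: float = 0.1,
    log2fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Cyclic-gene calls from centered log2 values of one level.

    A gene is cyclic iff its BH-adjusted ANOVA q-value is below
    ``q_threshold`` AND the maximum absolute log2 fold change between any
    two time-point means exceeds ``log2fc_threshold``.
    """
    meta = _check_samples(meta)
    counts = meta.groupby("time_point").size()
    if (counts < 2).any():
        raise ValueError("every time point needs >= 2 replicates for ANOVA")
    F, p, ssb, ssw, _, _ = _anova_sums_of_squares(centered, meta)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    means = timepoint_means(centered, meta)
    max_fc = (means.max(axis=1) - means.min(axis=1)).to_numpy()
    cyclic = (q < q_threshold) & (max_fc > log2fc_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssb_ssw = np.where(ssw > 0, ssb / ssw, np.inf)
    return pd.DataFrame(
        {
            "F": F,
            "p_value": p,
            "q_value": q,
            "max_abs_log2fc": max_fc,
            "cyclic": cyclic,
            "ssb": ssb,
            "ssw": ssw,
            "ssb_ssw": ssb_ssw,
        },
        index=centered.index,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson r between row profiles.

    Rows with zero variance get distance 1 to everything (with a warning):
    a flat profile is uncorrelated with any shape.
    """
    sd = profiles.std(axis=1)
    flat = sd <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant profile(s); assigned distance 1 to all",
            stacklevel=2,
        )
    safe = profiles.copy()
    safe[flat] = 0.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(safe)
    d = 1.0 - r
    d[flat, :] = 1.0
    d[:, flat] = 1.0
    np.fill_diagonal(d, 0.0)
    # numerical symmetry for squareform
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def cluster_cyclic(
    profiles: pd.DataFrame,
    timepoint_hours: np.ndarray | None = None,
    k: int = 4,
) -> tuple[pd.Series, float | None]:
    """Hierarchically cluster cyclic-gene mean profiles into G1..Gk.

    Distance is 1 - Pearson correlation; linkage is Ward (ward.D2-style on
    these distances). Labels are ordered by the circular peak time of each
    cluster's mean profile, so G1 peaks earliest in the cycle. Returns
    (labels, average silhouette width); the silhouette is None for k < 2 or
    when fewer than k+1 genes are available.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    if timepoint_hours is None:
        timepoint_hours = np.asarray(profiles.columns, dtype=float)
    arr = profiles.to_numpy(dtype=float)
    if k == 1:
        return pd.Series("G1", index=profiles.index), None
    dist = _correlation_distance(arr)
    z = linkage(squareform(dist, checks=False), method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")

    # order cluster ids by peak time of the mean profile
    order = []
    for cid in np.unique(raw):
        mean_profile = arr[raw == cid].mean(axis=0)
        order.append((timepoint_hours[int(np.argmax(mean_profile))], cid))
    order.sort()
    rename = {cid: f"G{rank + 1}" for rank, (_, cid) in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=profiles.index)

    sil = None
    if len(np.unique(raw)) >= 2 and len(profiles) > k:
        sil = float(silhouette_score(dist, raw, metric="precomputed"))
    return labels, sil


# ---------------------------------------------------------------------------
# amplitudes, correlations, turnover trend
# ---------------------------------------------------------------------------


def relative_amplitude(means: pd.DataFrame) -> pd.Series:
    """Peak-to-peak log2 fold change of time-point mean log2 values."""
    return means.max(axis=1) - means.min(axis=1)


def cross_level_correlation(
    centered_means_a: pd.DataFrame,
    centered_means_b: pd.DataFrame,
    genes: pd.Index | None = None,
):
    """Pooled Pearson r over gene x time-point centered mean values."""
    if genes is not None:
        centered_means_a = centered_means_a.loc[genes]
        centered_means_b = centered_means_b.loc[genes]
    a = centered_means_a.to_numpy(dtype=float).ravel()
    b = centered_means_b.to_numpy(dtype=float).ravel()
    if len(a) < 3:
        raise ValueError("need at least 3 pooled points for a correlation")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def turnover_trend(
    protein_amplitude: pd.Series,
    turnover_proxy: pd.Series,
    log_proxy: bool = True,
):
    """Correlation of protein relative amplitude with gene-specific turnover.

    The proxy is the daily-mean ribosome-footprint abundance over the
    daily-mean protein abundance (synthesis / abundance = turnover at
    steady state); by default it enters in log2, matching the wide dynamic
    range of per-gene turnover. Returns (Pearson r, p).
    """
    x = turnover_proxy.astype(float)
    if log_proxy:
        if (x <= 0).any():
            raise ValueError("turnover proxy must be positive for log scale")
        x = np.log2(x)
    y = protein_amplitude.astype(float)
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in amplitude or turnover proxy")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class DiurnalExpressionModel:
    """Multi-omics diurnal expression analysis.

    Parameters
    ----------
    mrna, ribo, protein : DataFrame
        Gene x sample abundance tables (positive scale: RPKM or normalized
        intensity). Columns are sample ids listed in ``samples``.
    samples : DataFrame
        Sample sheet with columns sample_id, level, time_point, replicate.
    mrna_total_counts, ribo_total_counts : Series, optional
        Per-gene total read counts for the minimum-count filters; when
        omitted those filters are skipped.
    timepoint_hours : mapping, optional
        Time (h) of each time_point id, used to order cluster labels by
        peak time. Defaults to the sorted time_point ids themselves.
    """

    def __init__(
        self,
        mrna: pd.DataFrame,
        ribo: pd.DataFrame,
        protein: pd.DataFrame,
        samples: pd.DataFrame,
        mrna_total_counts: pd.Series | None = None,
        ribo_total_counts: pd.Series | None = None,
        q_threshold: float = 0.1,
        log2fc_threshold: float = 1.0,
        n_clusters: int = 4,
        timepoint_hours: dict | None = None,
    ):
        self.tables = {"mrna": mrna, "ribo": ribo, "protein": protein}
        self.samples = _check_samples(samples)
        self.mrna_total_counts = mrna_total_counts
        self.ribo_total_counts = ribo_total_counts
        self.q_threshold = q_threshold
        self.log2fc_threshold = log2fc_threshold
        self.n_clusters = n_clusters
        self.timepoint_hours = timepoint_hours

    def fit(self) -> "DiurnalExpressionResults":
        retained, attrition = filter_genes(
            self.tables,
            self.samples,
            self.mrna_total_counts,
            self.ribo_total_counts,
        )
        centered, means, abundance_means = {}, {}, {}
        for level in LEVELS:
            meta = _level_meta(self.samples, level)
            values = self.tables[level].loc[retained, meta["sample_id"]]
            centered[level] = log2_center(values)
            means[level] = timepoint_means(centered[level], meta)
            # daily-mean abundance on the linear scale via geometric tp means
            log2_means = timepoint_means(
                pd.DataFrame(
                    np.log2(values.to_numpy(float)),
                    index=values.index,
                    columns=values.columns,
                ),
                meta,
            )
            abundance_means[level] = (2.0 ** log2_means).mean(axis=1)

        mrna_meta = _level_meta(self.samples, "mrna")
        calls = call_cyclic(
            centered["mrna"], mrna_meta, self.q_threshold, self.log2fc_threshold
        )
        cyclic_genes = calls.index[calls["cyclic"]]

        tp_ids = np.asarray(sorted(self.samples["time_point"].unique()))
        if self.timepoint_hours is not None:
            tp_hours = np.asarray([self.timepoint_hours[t] for t in tp_ids], float)
        else:
            tp_hours = tp_ids.astype(float)

        clusters = pd.Series("G0", index=retained)
        silhouette = None
        if len(cyclic_genes) >= self.n_clusters:
            labels, silhouette = cluster_cyclic(
                means["mrna"].loc[cyclic_genes], tp_hours, k=self.n_clusters
            )
            clusters.loc[cyclic_genes] = labels

        gene_calls = calls.copy()
        gene_calls["cluster"] = clusters
        for level in LEVELS:
            gene_calls[f"ra_{level}_log2"] = relative_amplitude(means[level])
        gene_calls["turnover_proxy"] = (
            abundance_means["ribo"] / abundance_means["protein"]
        )

        correlations = {}
        for pair in (("mrna", "ribo"), ("ribo", "protein"), ("mrna", "protein")):
            if len(cyclic_genes) >= 2:
                correlations[pair] = cross_level_correlation(
                    means[pair[0]], means[pair[1]], cyclic_genes
                )
        trend = None
        if len(cyclic_genes) >= 3:
            sub = gene_calls.loc[cyclic_genes]
            try:
                trend = turnover_trend(
                    sub["ra_protein_log2"], sub["turnover_proxy"]
                )
            except ValueError:
                trend = None

        medians = {
            level: float(gene_calls.loc[cyclic_genes, f"ra_{level}_log2"].median())
            for level in LEVELS
        }
        return DiurnalExpressionResults(
            gene_calls=gene_calls,
            centered=centered,
            timepoint_mean_profiles=means,
            attrition=attrition,
            silhouette=silhouette,
            correlations=correlations,
            turnover_trend=trend,
            median_amplitudes_log2=medians,
            timepoint_hours=dict(zip(tp_ids.tolist(), tp_hours.tolist())),
        )


@dataclass
class DiurnalExpressionResults:
    """Per-gene calls plus dataset-level diagnostics from the pipeline."""

    gene_calls: pd.DataFrame
    centered: dict[str, pd.DataFrame]
    timepoint_mean_profiles: dict[str, pd.DataFrame]
    attrition: pd.DataFrame
    silhouette: float | None
    correlations: dict[tuple[str, str], tuple[float, float]]
    turnover_trend: tuple[float, float] | None
    median_amplitudes_log2: dict[str, float]
    timepoint_hours: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_calls)

    @property
    def n_cyclic(self) -> int:
        return int(self.gene_calls["cyclic"].sum())

    @property
    def cyclic_fraction(self) -> float:
        return self.n_cyclic / self.n_genes

    def summary(self) -> str:
        lines = [
            "Diurnal multi-omics analysis",
            "============================",
            f"genes analysed            {self.n_genes:6d}",
            f"cyclic genes              {self.n_cyclic:6d} "
            f"({100 * self.cyclic_fraction:.0f}%)",
        ]
        if self.silhouette is not None:
            lines.append(f"cluster silhouette (k)    {self.silhouette:6.2f}")
        for level in LEVELS:
            med = self.median_amplitudes_log2[level]
            lines.append(
                f"median amplitude {level:<8} {2 ** med:6.2f}-fold "
                f"(log2 {med:.2f})"
            )
        for (a, b), (r, _) in self.correlations.items():
            lines.append(f"pooled r {a}-{b:<12} {r:6.2f}")
        if self.turnover_trend is not None:
            r, p = self.turnover_trend
            lines.append(f"amplitude~turnover trend  r={r:.2f}, p={p:.2g}")
        counts = self.gene_calls["cluster"].value_counts().sort_index()
        lines.append("cluster sizes             " + ", ".join(
            f"{k}:{v}" for k, v in counts.items()
        ))
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_cyclic": self.n_cyclic,
            "cyclic_fraction": self.cyclic_fraction,
            "silhouette": self.silhouette,
            "median_amplitudes_log2": self.median_amplitudes_log2,
            "correlations": {
                f"{a}_{b}": {"r": r, "p": p}
                for (a, b), (r, p) in self.correlations.items()
            },
            "turnover_trend": (
                None
                if self.turnover_trend is None
                else {"r": self.turnover_trend[0], "p": self.turnover_trend[1]}
            ),
        }
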