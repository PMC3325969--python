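"""miRNA expression signature procedures.

Per-study differential direction calls (two-sample t-test on
log-intensities, mesenchymal minus epithelial), cross-study consensus at
a minimum-study threshold, probe-replicate merging, average Pearson
correlation against the miR-200 family with rank assignment, and the
time-course replicate filter (|log-ratio| >= 0.5 and p <= 0.01, average
over passing replicates only).

The default family list is the five canonical miR-200 members from both
genomic clusters.  Raw p-value thresholds are applied, matching the
original procedures; Benjamini-Hochberg adjustment is offered as a
clearly optional extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MIR200_FAMILY",
    "ExpressionMatrix",
    "StudySignature",
    "MetaSignature",
    "CorrelationReport",
    "differential_signature",
    "intersect_signatures",
    "merge_replicates",
    "family_correlation_rank",
    "timepoint_de_filter",
]

#: both miR-200 genomic clusters: 200b/200a/429 and 200c/141
MIR200_FAMILY = (
    "hsa-miR-200a",
    "hsa-miR-200b",
    "hsa-miR-200c",
    "hsa-miR-141",
    "hsa-miR-429",
)

EPITHELIAL = "epithelial"
MESENCHYMAL = "mesenchymal"


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log-intensity (or log-ratio) values.

    ``values`` holds the matrix (index = feature ids, columns = sample
    ids; NaN marks missing values); ``sample_labels`` maps each sample
    to "epithelial" or "mesenchymal" (may be absent for unlabeled data).
    """

    values: pd.DataFrame
    sample_labels: pd.Series | None = None

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.sample_labels is not None:
            self.sample_labels = self.sample_labels.reindex(self.values.columns)
            missing = self.sample_labels.isna()
            if missing.any():
                raise ValueError(
                    f"samples without labels: {list(self.values.columns[missing])}"
                )
            bad = set(self.sample_labels.unique()) - {EPITHELIAL, MESENCHYMAL}
            if bad:
                raise ValueError(f"unknown sample labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path, annotation_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")
        if annotation_path is not None and self.sample_labels is not None:
            self.sample_labels.rename("label").to_csv(
                annotation_path, sep="\t", index_label="sample_id"
            )

    @classmethod
    def from_tsv(cls, path, annotation_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        labels = None
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
            labels = ann.iloc[:, 0]
        return cls(values, labels)


@dataclass
class StudySignature:
    """Per-miRNA t statistics, p-values, direction calls and significance.

    ``table`` columns: t, p, direction ("UP"/"DOWN"), significant, tested.
    Direction is the sign of mean(mesenchymal) - mean(epithelial).
    """

    table: pd.DataFrame
    alpha: float

    @property
    def significant_down(self) -> set[str]:
        t = self.table
        return set(t.index[t.significant & (t.direction == "DOWN")])

    @property
    def significant_up(self) -> set[str]:
        t = self.table
        return set(t.index[t.significant & (t.direction == "UP")])


@dataclass
class MetaSignature:
    """Cross-study consensus: per-miRNA study counts and the consensus set."""

    counts: pd.DataFrame  # columns: down_count, up_count
    consensus: set[str]
    direction: str
    min_studies: int
    n_studies: int
    pairwise_overlap: pd.DataFrame
    overall_overlap: int


@dataclass
class CorrelationReport:
    """Average Pearson correlation with the miR-200 family, with ranks.

    ``table`` columns: avg_correlation (NaN for zero-variance features),
    rank (1 = highest average; NaN averages rank last; ties broken by
    feature id).
    """

    table: pd.DataFrame
    family_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# differential signatures
# ---------------------------------------------------------------------------


def differential_signature(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    equal_var: bool = False,
    fdr: bool = False,
) -> StudySignature:
    """Two-sided two-sample t-test per miRNA between E and M samples.

    Welch's test by default (``equal_var=True`` for the pooled-variance
    flavour).  Direction is UP when the mesenchymal mean exceeds the
    epithelial mean, DOWN otherwise.  A miRNA with fewer than 2
    non-missing values in either group is reported untested.  With
    ``fdr=True`` significance is called on Benjamini-Hochberg adjusted
    p-values instead of raw ones (an extension over the original raw
    threshold).
    """
    if matrix.sample_labels is None:
        raise ValueError("matrix has no epithelial/mesenchymal sample labels")
    lab = matrix.sample_labels
    epi = matrix.values.loc[:, lab == EPITHELIAL]
    mes = matrix.values.loc[:, lab == MESENCHYMAL]

    rows = []
    for fid in matrix.feature_ids:
        e = epi.loc[fid].dropna().to_numpy(dtype=float)
        m = mes.loc[fid].dropna().to_numpy(dtype=float)
        if len(e) < 2 or len(m) < 2:
            rows.append((fid, np.nan, np.nan, None, False, False))
            continue
        diff = m.mean() - e.mean()
        if np.var(e) == 0 and np.var(m) == 0 and diff == 0:
            t, p = 0.0, 1.0  # two identical constant groups: no evidence
        else:
            t, p = stats.ttest_ind(m, e, equal_var=equal_var)
        direction = "UP" if diff > 0 else "DOWN"
        rows.append((fid, float(t), float(p), direction, False, True))
    table = pd.DataFrame(
        rows, columns=["feature_id", "t", "p", "direction", "significant", "tested"]
    ).set_index("feature_id")

    tested = table.tested & table.p.notna()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        adj = pd.Series(np.nan, index=table.index)
        if tested.any():
            adj.loc[tested] = multipletests(table.p[tested], method="fdr_bh")[1]
        table["p_adjusted"] = adj
        table.loc[tested, "significant"] = adj[tested] < alpha
    else:
        table.loc[tested, "significant"] = table.p[tested] < alpha
    table["significant"] = table.significant.astype(bool)
    return StudySignature(table=table, alpha=alpha)


def intersect_signatures(
    signatures: Sequence[StudySignature],
    direction: str = "DOWN",
    min_studies: int = 3,
) -> MetaSignature:
    """Count, per miRNA, studies calling it significant in each direction.

    The consensus set keeps miRNAs significant in the requested
    *direction* in at least *min_studies* studies.  Pairwise and overall
    overlap counts of the per-study directional sets (the Venn numbers)
    are included.
    """
    if not signatures:
        raise ValueError("need at least one study signature")
    if direction not in ("UP", "DOWN"):
        raise ValueError("direction must be 'UP' or 'DOWN'")
    all_ids = sorted(set().union(*(set(s.table.index) for s in signatures)))
    down = pd.Series(0, index=all_ids)
    up = pd.Series(0, index=all_ids)
    sets = []
    for s in signatures:
        d, u = s.significant_down, s.significant_up
        down.loc[sorted(d)] += 1
        up.loc[sorted(u)] += 1
        sets.append(d if direction == "DOWN" else u)
    counts = pd.DataFrame({"down_count": down, "up_count": up})
    wanted = down if direction == "DOWN" else up
    consensus = set(counts.index[wanted >= min_studies])
    k = len(sets)
    overlap = pd.DataFrame(
        [[len(sets[i] & sets[j]) for j in range(k)] for i in range(k)],
        index=range(1, k + 1),
        columns=range(1, k + 1),
    )
    overall = len(set.intersection(*sets)) if sets else 0
    return MetaSignature(
        counts=counts,
        consensus=consensus,
        direction=direction,
        min_studies=min_studies,
        n_studies=k,
        pairwise_overlap=overlap,
        overall_overlap=overall,
    )


# ---------------------------------------------------------------------------
# replicate merging and family correlation
# ---------------------------------------------------------------------------


def merge_replicates(
    matrix: ExpressionMatrix, id_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Average probe rows that map to the same canonical miRNA id.

    Features missing from *id_map* pass through unchanged; missing
    values are ignored in the per-sample mean.
    """
    canonical = [id_map.get(f, f) for f in matrix.feature_ids]
    merged = matrix.values.groupby(
        pd.Index(canonical, name=matrix.values.index.name)
    ).mean()
    # keep first-appearance order of the canonical ids
    seen: list[str] = []
    for c in canonical:
        if c not in seen:
            seen.append(c)
    merged = merged.loc[seen]
    return ExpressionMatrix(merged, matrix.sample_labels)


def family_correlation_rank(
    matrix: ExpressionMatrix,
    family_ids: Iterable[str] = MIR200_FAMILY,
) -> CorrelationReport:
    """Rank every miRNA by its average Pearson correlation with the family.

    The full feature-feature Pearson matrix is computed; each miRNA's
    correlations with the family members are averaged (excluding its
    self-correlation when it belongs to the family) and ranks assigned
    in descending order of the average — the higher the average
    correlation, the lower (better) the rank.  Zero-variance features
    have undefined correlations and rank last; ties break by feature id.
    """
    family = tuple(sorted(set(family_ids)))
    missing = set(family) - set(matrix.feature_ids)
    if missing:
        raise ValueError(f"family members absent from the matrix: {sorted(missing)}")
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation analysis")

    corr = matrix.values.T.corr(method="pearson")  # features x features
    fam_corr = corr.loc[:, list(family)].copy()
    for f in family:  # exclude self-correlation of family members
        fam_corr.loc[f, f] = np.nan
    avg = fam_corr.mean(axis=1, skipna=True)
    # features with zero variance have all-NaN correlations -> NaN average
    order = sorted(avg.index, key=lambda f: (np.isnan(avg[f]), -avg[f] if not np.isnan(avg[f]) else 0.0, f))
    rank = pd.Series({f: i + 1 for i, f in enumerate(order)})
    table = pd.DataFrame({"avg_correlation": avg, "rank": rank})
    table = table.sort_values("rank")
    return CorrelationReport(table=table, family_ids=family)


# ---------------------------------------------------------------------------
# time-course replicate filter
# ---------------------------------------------------------------------------


def timepoint_de_filter(
    log_ratios: pd.DataFrame,
    min_abs: float = 0.5,
    max_p: float = 0.01,
) -> pd.DataFrame:
    """Average replicate log-ratios per (miRNA, time point) after filtering.

    *log_ratios* is a long table with columns ``mirna``, ``time_point``,
    ``log_ratio`` and either a precomputed ``p_value`` column or a
    ``probe_ratios`` column holding each replicate's probe-level ratios
    (list-like), from which a one-sample t-test against 0 supplies the
    p-value.  A replicate passes iff |log_ratio| >= *min_abs* and
    p <= *max_p*; the average is taken over passing replicates only.

    Returns a table indexed by (mirna, time_point) with columns
    ``average`` (NaN when no replicate passes), ``n_pass``, ``n_total``,
    ``present`` and ``testable`` (False when fewer than 2 replicates).
    """
    df = log_ratios.copy()
    required = {"mirna", "time_point", "log_ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"log_ratios must have columns {sorted(required)}")
    if "p_value" not in df.columns:
        if "probe_ratios" not in df.columns:
            raise ValueError("need a 'p_value' or 'probe_ratios' column")
        pvals = []
        for probes in df.probe_ratios:
            arr = np.asarray(probes, dtype=float)
            if len(arr) < 2:
                pvals.append(np.nan)
            else:
                pvals.append(float(stats.ttest_1samp(arr, 0.0).pvalue))
        df["p_value"] = pvals

    rows = []
    for (mirna, tp), grp in df.groupby(["mirna", "time_point"], sort=True):
        n_total = len(grp)
        testable = n_total >= 2
        if not testable:
            rows.append((mirna, tp, np.nan, 0, n_total, False, False))
            continue
        ok = (grp.log_ratio.abs() >= min_abs) & (grp.p_value <= max_p)
        n_pass = int(ok.sum())
        avg = float(grp.log_ratio[ok].mean()) if n_pass else np.nan
        rows.append((mirna, tp, avg, n_pass, n_total, n_pass > 0, True))
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "time_point", "average", "n_pass", "n_total",
            "present", "testable",
        ],
    ).set_index(["mirna", "time_point"])
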