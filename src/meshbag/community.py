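"""Post-clustering processing of fungal ITS OTU tables.

Implements the community stage downstream of sequence clustering: the
similarity/coverage rule that assigns taxonomic rank from BLAST-style
hit tables, removal of rare OTUs, averaging of technical replicates,
rarefaction to a common read depth, relative-abundance and guild
profiles, Bray-Curtis dissimilarities, and PERMANOVA on the resulting
distance matrix.

The canonical processing order is: filter rare OTUs on the raw count
matrix, average technical replicates, rarefy to the (lower) median
column sum, then convert to relative abundances — see
:func:`process_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

GUILDS = ("ECM", "saprotroph", "pathogen", "unknown")


@dataclass
class OtuTable:
    """OTU x sample-column count matrix with annotations.

    ``counts`` has OTU ids as the index and sample columns;
    ``replicate_groups`` maps each column to its biological sample;
    ``taxonomy``/``guild`` map OTU ids to labels.  ``meta`` accumulates
    processing provenance (filter logs, rarefaction depth, seeds).
    """

    counts: pd.DataFrame
    replicate_groups: dict[str, str] | None = None
    taxonomy: dict[str, str] | None = None
    guild: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.empty:
            raise ValueError("counts must be a non-empty OTU x sample matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.replicate_groups is not None:
            missing = set(self.counts.columns) - set(self.replicate_groups)
            if missing:
                raise ValueError(f"columns without a replicate group: {sorted(missing)}")

    @property
    def n_otus(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.counts.shape[1])


@dataclass(frozen=True)
class BlastHit:
    """One OTU's top database hit: percent identity, percent coverage."""

    otu: str
    identity_pct: float
    coverage_pct: float
    hit_name: str = ""

    def __post_init__(self) -> None:
        for value, name in ((self.identity_pct, "identity"),
                            (self.coverage_pct, "coverage")):
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} percentage {value} outside [0, 100]")


def assign_rank(hit: BlastHit) -> str:
    """Taxonomic rank warranted by a hit's similarity and coverage.

    >= 96% identity with >= 80% coverage supports a species-level name;
    94-95.99% identity with >= 80% coverage supports genus only;
    anything else is unassigned.  The coverage gate applies to both
    tiers.
    """
    if hit.coverage_pct >= 80.0:
        if hit.identity_pct >= 96.0:
            return "species"
        if hit.identity_pct >= 94.0:
            return "genus"
    return "unassigned"


def filter_rare_otus(t: OtuTable, min_reads: int = 10, min_samples: int = 2,
                     mode: str = "either") -> OtuTable:
    """Remove rare OTUs from the raw count matrix.

    Under the default ``mode="either"`` an OTU is removed if its total
    reads are below ``min_reads`` OR it occurs in fewer than
    ``min_samples`` columns; ``mode="both"`` removes only OTUs failing
    both conditions.  The removed ids and the mode are recorded in the
    result's ``meta["filter_log"]``.
    """
    if mode not in ("either", "both"):
        raise ValueError(f"unknown filter mode {mode!r}")
    totals = t.counts.sum(axis=1)
    occupancy = (t.counts > 0).sum(axis=1)
    low_reads = totals < min_reads
    few_samples = occupancy < min_samples
    remove = (low_reads | few_samples) if mode == "either" else (low_reads & few_samples)
    removed = list(t.counts.index[remove])
    kept = t.counts.loc[~remove]
    if kept.empty:
        raise ValueError("rare-OTU filter removed every OTU")
    meta = dict(t.meta)
    meta["filter_log"] = {
        "mode": mode, "min_reads": min_reads, "min_samples": min_samples,
        "removed": removed,
    }
    return replace(t, counts=kept, meta=meta)


def average_replicates(t: OtuTable) -> OtuTable:
    """Average technical-replicate columns into one column per sample.

    The result's entries are arithmetic means and may be non-integer;
    :func:`rarefy` rounds before subsampling.
    """
    if not t.replicate_groups:
        raise ValueError("no replicate groups defined")
    groups: dict[str, list[str]] = {}
    for col in t.counts.columns:
        groups.setdefault(t.replicate_groups[col], []).append(col)
    for sample, cols in groups.items():
        if not cols:
            raise ValueError(f"replicate group {sample!r} is empty")
    averaged = pd.DataFrame(
        {sample: t.counts[cols].mean(axis=1) for sample, cols in groups.items()},
        index=t.counts.index,
    )
    meta = dict(t.meta)
    meta["replicates_averaged"] = {s: len(c) for s, c in groups.items()}
    return replace(t, counts=averaged,
                   replicate_groups={s: s for s in groups}, meta=meta)


def median_depth(t: OtuTable) -> int:
    """Lower median of the column sums — an always-achievable depth."""
    sums = np.sort(np.rint(t.counts.sum(axis=0).to_numpy()).astype(np.int64))
    return int(sums[(len(sums) - 1) // 2])


def rarefy(t: OtuTable, depth: int | None = None, seed: int | None = None,
           on_shallow: str = "error") -> OtuTable:
    """Subsample every column without replacement to a common depth.

    ``depth`` defaults to the lower median of the column sums.  Columns
    whose (rounded) sum falls below the depth raise an error naming the
    sample, or are dropped under ``on_shallow="drop"``.  Averaged
    (real-valued) counts are rounded to the nearest integer first, since
    subsampling needs integer reads.
    """
    if on_shallow not in ("error", "drop"):
        raise ValueError(f"unknown shallow-sample policy {on_shallow!r}")
    ints = np.rint(t.counts.to_numpy()).astype(np.int64)
    if depth is None:
        sums = np.sort(ints.sum(axis=0))
        depth = int(sums[(len(sums) - 1) // 2])
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for j, col in enumerate(t.counts.columns):
        colsum = int(ints[:, j].sum())
        if colsum < depth:
            if on_shallow == "drop":
                continue
            raise ValueError(
                f"sample {col!r} has {colsum} reads, below rarefaction depth {depth}"
            )
        if colsum == depth:
            out[col] = ints[:, j]
        else:
            out[col] = rng.multivariate_hypergeometric(ints[:, j], depth)
    if not out:
        raise ValueError("no sample reaches the rarefaction depth")
    rarefied = pd.DataFrame(out, index=t.counts.index)
    meta = dict(t.meta)
    meta["rarefaction"] = {"depth": int(depth), "seed": seed,
                           "dropped": [c for c in t.counts.columns if c not in out]}
    groups = None
    if t.replicate_groups is not None:
        groups = {c: t.replicate_groups[c] for c in rarefied.columns}
    return replace(t, counts=rarefied, replicate_groups=groups, meta=meta)


def relative_abundance(t: OtuTable) -> OtuTable:
    """Scale each column to sum to 1."""
    sums = t.counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {list(zero.index)}")
    return replace(t, counts=t.counts / sums)


def guild_profile(t: OtuTable, display_min_reads: int = 50
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample guild relative abundances and a display OTU subset.

    Returns a guild x sample table of fractions summing to 1 per sample,
    plus the ids of OTUs with strictly more than ``display_min_reads``
    total reads (the visualization cutoff).
    """
    if t.guild is None:
        raise ValueError("no guild annotations on this table")
    missing = set(t.counts.index) - set(t.guild)
    if missing:
        raise ValueError(f"OTUs without guild annotation: {sorted(missing)[:5]}")
    sums = t.counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {list(zero.index)}")
    labels = pd.Series({otu: t.guild[otu] for otu in t.counts.index})
    profile = t.counts.groupby(labels).sum() / sums
    profile = profile.reindex([g for g in GUILDS if g in profile.index])
    display = list(t.counts.index[t.counts.sum(axis=1) > display_min_reads])
    return profile, display


def process_counts(t: OtuTable, min_reads: int = 10, min_samples: int = 2,
                   filter_mode: str = "either", depth: int | None = None,
                   seed: int | None = None, on_shallow: str = "error") -> OtuTable:
    """The canonical pipeline: filter -> average replicates -> rarefy ->
    relative abundance."""
    t = filter_rare_otus(t, min_reads=min_reads, min_samples=min_samples,
                         mode=filter_mode)
    if t.replicate_groups is not None:
        t = average_replicates(t)
    t = rarefy(t, depth=depth, seed=seed, on_shallow=on_shallow)
    return relative_abundance(t)


# ---------------------------------------------------------------------
# Dissimilarity and PERMANOVA
# ---------------------------------------------------------------------

def bray_curtis(t: OtuTable | pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns.

    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j); symmetric, zero diagonal,
    bounded in [0, 1].  Undefined (and rejected) when two all-zero
    samples are compared.
    """
    if isinstance(t, OtuTable):
        counts = t.counts
    elif isinstance(t, pd.DataFrame):
        counts = t
    else:
        counts = pd.DataFrame(np.asarray(t, dtype=float))
    X = counts.to_numpy(dtype=float).T  # samples x OTUs
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) <= 0).sum() >= 2:
        raise ValueError("two all-zero samples: Bray-Curtis undefined")
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


@dataclass(frozen=True)
class PermanovaResult:
    """PERMANOVA outcome: pseudo-F, R-squared and a permutation p-value."""

    f_statistic: float
    r_squared: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 outside [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value outside (0, 1]")


def _permanova_ss(d2: np.ndarray, labels: np.ndarray,
                  group_ids: np.ndarray) -> tuple[float, float]:
    """(SS_among, SS_within) from squared dissimilarities and labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in group_ids:
        idx = labels == g
        n_g = int(idx.sum())
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return ss_total - ss_within, ss_within


def permanova(d: pd.DataFrame | np.ndarray, groups, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Uses the distance-based pseudo-F: with N samples in a groups,
    SS_total = sum of squared dissimilarities / N, SS_within the
    analogous within-group sum, F = (SS_among/(a-1)) / (SS_within/(N-a)),
    R^2 = SS_among/SS_total, and p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) from free permutation of the group labels.
    """
    D = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    labels = np.asarray(list(groups))
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one group label per sample required")
    group_ids, counts = np.unique(labels, return_counts=True)
    a = len(group_ids)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = group_ids[counts < 2]
        raise ValueError(f"singleton groups not allowed: {list(small)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = D ** 2
    ss_among, ss_within = _permanova_ss(d2, labels, group_ids)
    ss_total = ss_among + ss_within
    if ss_total <= 0:
        raise ValueError("all dissimilarities are zero")
    f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))

    rng = np.random.default_rng(seed)
    # Vectorized permutations: boolean membership matrices per group.
    perms = np.argsort(rng.random((n_perm, n)), axis=1)  # n_perm random orders
    perm_labels = labels[perms]                          # n_perm x n
    ss_within_perm = np.zeros(n_perm)
    for g, n_g in zip(group_ids, counts):
        M = (perm_labels == g).astype(float)             # n_perm x n
        ss_within_perm += np.einsum("pi,ij,pj->p", M, d2, M) / (2.0 * n_g)
    ss_among_perm = ss_total - ss_within_perm
    f_perm = (ss_among_perm / (a - 1)) / (ss_within_perm / (n - a))
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)

    return PermanovaResult(
        f_statistic=float(f_obs),
        r_squared=float(ss_among / ss_total),
        p_value=float(p),
        n_permutations=int(n_perm),
    )


# ---------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------

def read_otu_table(counts_tsv, guild_tsv=None, taxonomy_tsv=None,
                   replicate_tsv=None) -> OtuTable:
    """Read an OTU table from TSV files (OTUs as rows, first column id)."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    guild = taxonomy = groups = None
    if guild_tsv is not None:
        s = pd.read_csv(guild_tsv, sep="\t", index_col=0).iloc[:, 0]
        guild = s.to_dict()
    if taxonomy_tsv is not None:
        s = pd.read_csv(taxonomy_tsv, sep="\t", index_col=0).iloc[:, 0]
        taxonomy = s.to_dict()
    if replicate_tsv is not None:
        s = pd.read_csv(replicate_tsv, sep="\t", index_col=0).iloc[:, 0]
        groups = s.to_dict()
    return OtuTable(counts=counts, replicate_groups=groups,
                    taxonomy=taxonomy, guild=guild)


def write_otu_table(t: OtuTable, counts_tsv) -> None:
    t.counts.to_csv(counts_tsv, sep="\t")
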