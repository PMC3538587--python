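"""Read filtering and OTU-table diversity comparison.

Implements the downstream community-comparison chain for amplicon surveys:
quality filtering of pyrosequencing reads, removal of rare OTUs (singletons
and doubletons), fixed-depth replicate subsampling so samples of unequal
sequencing effort are comparable, alpha-diversity metrics (observed OTUs,
Shannon H, equitability, Chao1), rarefaction curves, Bray-Curtis
dissimilarity on phylum-level relative abundances, and UPGMA clustering of
the resulting distance matrix.

OTU clustering itself (UCLUST/DOTUR runs on raw sequences) is an external
step; tables at a stated similarity level are inputs here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from skbio import TreeNode

__all__ = [
    "ReadRecord", "OTUTable", "DiversityReport",
    "read_fastq", "filter_reads", "drop_rare_otus", "subsample_replicates",
    "alpha_metrics", "rarefaction_curve", "collapse_phylum", "bray_curtis",
    "upgma", "diversity_report",
]

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass
class ReadRecord:
    """A sequencing read with per-base qualities.

    ``primer_mismatches`` is the number of 5'-end mismatches against the
    amplification primer; it can be supplied directly or recomputed by
    :func:`filter_reads` when a primer sequence is given.
    """

    identifier: str
    sequence: str
    qualities: list[int]
    primer_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.identifier}: sequence/quality length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.identifier}: negative quality score")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities))

    @property
    def max_homopolymer(self) -> int:
        best = run = 1
        seq = self.sequence
        for i in range(1, len(seq)):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            best = max(best, run)
        return best if seq else 0


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load reads from a FASTQ file (Sanger/Phred+33 qualities)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            ReadRecord(
                rec.id, str(rec.seq).upper(),
                list(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def count_primer_mismatches(sequence: str, primer: str) -> int:
    """Mismatches of the read 5' end against a primer with IUPAC ambiguity."""
    mismatches = 0
    for i, p in enumerate(primer.upper()):
        base = sequence[i].upper() if i < len(sequence) else None
        allowed = _IUPAC.get(p)
        if allowed is None:
            raise ValueError(f"invalid primer symbol {p!r}")
        if base is None or base not in allowed:
            mismatches += 1
    return mismatches


def filter_reads(
    reads: list[ReadRecord],
    min_mean_q: float = 25.0,
    max_homopolymer: int = 6,
    max_primer_mismatch: int = 0,
    min_len: int = 200,
    max_len: int = 1000,
    primer: str | None = None,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply the standard pyrosequencing quality filter.

    A read is kept iff its mean quality score is >= ``min_mean_q``, its
    longest single-base run is <= ``max_homopolymer``, its primer mismatch
    count is <= ``max_primer_mismatch`` and its length is within
    [``min_len``, ``max_len``]. Rejection counts attribute each rejected read
    to every criterion it fails.
    """
    kept: list[ReadRecord] = []
    rejected = {"quality": 0, "homopolymer": 0, "primer": 0, "length": 0}
    for read in reads:
        mismatches = (
            count_primer_mismatches(read.sequence, primer)
            if primer is not None
            else read.primer_mismatches
        )
        fails = []
        if read.mean_quality < min_mean_q:
            fails.append("quality")
        if read.max_homopolymer > max_homopolymer:
            fails.append("homopolymer")
        if mismatches > max_primer_mismatch:
            fails.append("primer")
        if not min_len <= len(read.sequence) <= max_len:
            fails.append("length")
        if fails:
            for f in fails:
                rejected[f] += 1
        else:
            kept.append(read)
    return kept, rejected


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

@dataclass
class OTUTable:
    """Sample × OTU counts with optional phylum labels.

    counts: DataFrame with OTU identifiers as the index and sample
    identifiers as columns (non-negative integers). phylum: optional Series
    mapping OTU id -> phylum label. similarity: the clustering identity level
    the table was built at (e.g., 0.97).
    """

    counts: pd.DataFrame
    phylum: pd.Series | None = None
    similarity: float | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.phylum is not None:
            self.phylum = self.phylum.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path: str | Path, similarity: float | None = None) -> "OTUTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        phylum = None
        if "phylum" in df.columns:
            phylum = df.pop("phylum")
        return cls(df, phylum=phylum, similarity=similarity)

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        if self.phylum is not None:
            df["phylum"] = self.phylum
        df.to_csv(path, sep="\t")


def drop_rare_otus(table: OTUTable, max_count: int = 2) -> OTUTable:
    """Remove OTUs with total count <= ``max_count`` (singletons/doubletons)."""
    totals = table.counts.sum(axis=1)
    keep = totals > max_count
    phylum = table.phylum[keep] if table.phylum is not None else None
    return OTUTable(table.counts.loc[keep], phylum=phylum, similarity=table.similarity)


def _subsample_column(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multivariate_hypergeometric(counts, depth)


def subsample_replicates(
    table: OTUTable, depth: int = 1557, replicates: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[OTUTable]:
    """Draw fixed-depth subsamples (without replacement) per sample.

    Samples with fewer than ``depth`` sequences are dropped with a warning.
    Each replicate table has per-sample totals exactly equal to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = [s for s in table.samples if totals[s] >= depth]
    dropped = sorted(set(table.samples) - set(keep))
    if dropped:
        warnings.warn(f"samples below depth {depth} dropped: {dropped}")
    counts = table.counts[keep]
    out = []
    for _ in range(replicates):
        sub = pd.DataFrame(
            {s: _subsample_column(counts[s].to_numpy(), depth, rng) for s in keep},
            index=counts.index,
        )
        out.append(OTUTable(sub, phylum=table.phylum, similarity=table.similarity))
    return out


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0  # bias-corrected form for F2 = 0


def alpha_metrics(table: OTUTable, log_base: float = np.e) -> pd.DataFrame:
    """Per-sample observed OTUs, Shannon H, equitability and Chao1.

    Shannon uses the natural log by default (``log_base`` switches it);
    equitability is H / log(observed) and defined as 0 for single-OTU
    samples.
    """
    rows = {}
    for sample in table.samples:
        counts = table.counts[sample].to_numpy()
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} is empty")
        present = counts[counts > 0]
        p = present / total
        h = float(-(p * np.log(p)).sum() / np.log(log_base))
        s_obs = len(present)
        equit = h / (np.log(s_obs) / np.log(log_base)) if s_obs > 1 else 0.0
        rows[sample] = {
            "observed_otus": s_obs,
            "shannon": h,
            "equitability": float(equit),
            "chao1": _chao1(counts),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _expected_richness(counts: np.ndarray, depth: int) -> float:
    """Analytic rarefaction: E[S_d] = Σ_i (1 - C(N-n_i, d)/C(N, d))."""
    counts = counts[counts > 0]
    N = int(counts.sum())
    if depth > N:
        raise ValueError(f"depth {depth} exceeds sample total {N}")

    def log_comb(n: int | np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    terms = np.where(
        N - counts >= depth,
        np.exp(log_comb(N - counts, depth) - log_comb(N, depth)),
        0.0,
    )
    return float((1.0 - terms).sum())


def rarefaction_curve(
    table: OTUTable, depths: list[int], reps: int = 10,
    seed: int = 0, mode: str = "analytic",
) -> pd.DataFrame:
    """Expected observed richness per sample at each subsampling depth.

    ``mode="analytic"`` evaluates the exact hypergeometric expectation;
    ``mode="montecarlo"`` averages ``reps`` random subsamples.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for sample in table.samples:
        counts = table.counts[sample].to_numpy()
        richness = []
        for d in depths:
            if mode == "analytic":
                richness.append(_expected_richness(counts, d))
            elif mode == "montecarlo":
                obs = [
                    int((_subsample_column(counts, d, rng) > 0).sum())
                    for _ in range(reps)
                ]
                richness.append(float(np.mean(obs)))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        rows[sample] = richness
    return pd.DataFrame(rows, index=pd.Index(depths, name="depth"))


def collapse_phylum(table: OTUTable) -> pd.DataFrame:
    """Sum counts per phylum (rows) across samples; unlabelled -> 'unclassified'."""
    if table.phylum is None:
        raise ValueError("table has no phylum labels")
    labels = table.phylum.fillna("unclassified")
    return table.counts.groupby(labels).sum()


def bray_curtis(table: OTUTable, level: str = "phylum") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on relative abundances.

    BC(a, b) = Σ|a_i - b_i| / Σ(a_i + b_i) after per-sample normalization;
    computed at phylum level by default, or directly on OTUs.
    """
    if level == "phylum":
        counts = collapse_phylum(table)
    elif level == "otu":
        counts = table.counts
    else:
        raise ValueError(f"unknown level {level!r}")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero samples: {empty}")
    rel = counts / totals
    samples = list(rel.columns)
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = rel.iloc[:, i].to_numpy()
            b = rel.iloc[:, j].to_numpy()
            mat[i, j] = mat[j, i] = np.abs(a - b).sum() / (a + b).sum()
    return pd.DataFrame(mat, index=samples, columns=samples)


def upgma(distance: pd.DataFrame) -> TreeNode:
    """Average-linkage (UPGMA) tree from a distance matrix.

    The tree is ultrametric: every leaf sits at half the final merge height.
    Samples are ordered lexicographically before clustering so ties break
    deterministically. Serialize with ``str(tree)`` (newick).
    """
    if distance.isna().values.any():
        raise ValueError("distance matrix contains NaN")
    labels = sorted(distance.columns)
    if len(labels) < 2:
        raise ValueError("need >=2 samples")
    d = distance.loc[labels, labels].to_numpy()
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="average")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]
    heights = [0.0] * len(labels)
    for left, right, merge_h, _ in Z:
        li, ri = int(left), int(right)
        h = merge_h / 2.0  # leaf-to-node distance in an ultrametric tree
        a, b = nodes[li], nodes[ri]
        a.length = h - heights[li]
        b.length = h - heights[ri]
        nodes.append(TreeNode(children=[a, b]))
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


@dataclass
class DiversityReport:
    """Replicate-averaged alpha metrics, beta-diversity matrix and UPGMA tree."""

    alpha_mean: pd.DataFrame
    alpha_std: pd.DataFrame
    bray_curtis: pd.DataFrame
    tree: TreeNode
    depth: int
    replicates: int

    @property
    def tree_newick(self) -> str:
        return str(self.tree).strip()


def diversity_report(
    table: OTUTable,
    depth: int = 1557,
    replicates: int = 10,
    seed: int = 0,
    drop_rare: bool = True,
) -> DiversityReport:
    """Run the full comparison procedure on one multi-sample OTU table.

    Rare OTUs (total count <= 2) are removed, each sample is subsampled to a
    common depth in ``replicates`` replicates, alpha metrics are averaged
    over replicates, and Bray-Curtis distances at phylum level feed a UPGMA
    tree.
    """
    work = drop_rare_otus(table) if drop_rare else table
    subs = subsample_replicates(work, depth=depth, replicates=replicates, seed=seed)
    if not subs or not subs[0].samples:
        raise ValueError("no samples meet the subsampling depth")
    alphas = [alpha_metrics(t) for t in subs]
    stacked = pd.concat(alphas, keys=range(len(alphas)))
    mean = stacked.groupby(level=1).mean().loc[subs[0].samples]
    std = stacked.groupby(level=1).std(ddof=0).loc[subs[0].samples]
    bc = bray_curtis(work)
    tree = upgma(bc)
    return DiversityReport(mean, std, bc, tree, depth, replicates)
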