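"""Strain-level SNV feature engineering from marker-gene alignments.

From a species MSA, the pipeline (1) keeps alignment columns whose
major-allele frequency has binary entropy >= 0.5 (strain-variable sites),
(2) optionally collapses duplicate site patterns within clusters of
near-identical samples (keeping the least-gapped site), (3) one-hot encodes
each kept site into five binary features (A, C, G, T, gap; N residues leave
all five at 0), (4) removes features with pooled prevalence outside
[20%, 80%] in the control+case samples, and (5) greedily prunes features
correlated (|Pearson phi| > 0.5) with an earlier-kept feature.  The
surviving binary matrix feeds a Jaccard-distance blocked PERMANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diversity import PermanovaResult, jaccard_matrix, permanova_blocked
from .io import MsaSet

logger = logging.getLogger(__name__)

SYMBOLS = ("A", "C", "G", "T", "-")
SYMBOL_NAMES = ("A", "C", "G", "T", "gap")


@dataclass
class StrainFeatureMatrix:
    """Binary samples x (sgb, position, symbol) matrix with provenance."""

    feature_ids: list[tuple]  # (sgb_id, 1-based position, symbol name)
    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_features) of {0, 1}
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_labels(self) -> list[str]:
        return [f"{s}:{p}:{sym}" for s, p, sym in self.feature_ids]

    def select(self, keep: np.ndarray, note: str) -> "StrainFeatureMatrix":
        keep = np.asarray(keep)
        prov = dict(self.provenance)
        prov.setdefault("funnel", []).append((note, int(keep.sum())))
        return StrainFeatureMatrix(
            feature_ids=[f for f, k in zip(self.feature_ids, keep) if k],
            sample_ids=list(self.sample_ids),
            values=self.values[:, keep],
            provenance=prov,
        )


def binary_entropy(p) -> float:
    """H(p) = -p log2 p - (1-p) log2(1-p), with 0 log 0 = 0 (bits)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("binary_entropy: p outside [0, 1]")
    out = np.zeros_like(arr)
    mask = (arr > 0) & (arr < 1)
    q = arr[mask]
    out[mask] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out if out.ndim else float(out)


def select_positions(msa: MsaSet, entropy_min: float = 0.5):
    """Strain-variable alignment columns: entropy of the major allele >= min.

    The major-allele frequency is computed over non-N symbols with the gap
    counted as an ordinary symbol; all-N columns are dropped.  Returns
    (positions, stats) with 1-based positions and per-position
    (major_freq, entropy).
    """
    arr = msa.to_array()
    if arr.size == 0:
        return [], {}
    positions = []
    stats = {}
    for j in range(arr.shape[1]):
        col = arr[:, j]
        informative = col[col != "N"]
        if informative.size == 0:
            continue
        _, counts = np.unique(informative, return_counts=True)
        p_major = counts.max() / informative.size
        h = float(binary_entropy(p_major))
        stats[j + 1] = (float(p_major), h)
        if h >= entropy_min:
            positions.append(j + 1)
    return positions, stats


def _pairwise_snp_distance(arr: np.ndarray) -> np.ndarray:
    """1 - identity over shared non-N columns, for sample clustering."""
    n = arr.shape[0]
    valid = arr != "N"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            m = int(shared.sum())
            if m == 0:
                d = 1.0
            else:
                d = 1.0 - float((arr[i, shared] == arr[j, shared]).sum()) / m
            D[i, j] = D[j, i] = d
    return D


def _single_linkage_clusters(D: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Connected components of the graph with edges at distance <= threshold."""
    n = D.shape[0]
    adj = D <= threshold
    unseen = set(range(n))
    clusters = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            nbrs = set(np.where(adj[i])[0]) & unseen
            unseen -= nbrs
            comp |= nbrs
            frontier.extend(nbrs)
        clusters.append(np.array(sorted(comp)))
    return clusters


def _partition_signature(column: np.ndarray) -> tuple:
    """Canonical label sequence of the sample partition a column induces.

    Two columns with the same signature split the samples identically (their
    one-hot features are perfectly correlated) even if the residues differ,
    e.g. A/A/C/C and G/G/-/-.
    """
    mapping: dict[str, int] = {}
    out = []
    for ch in column:
        if ch not in mapping:
            mapping[ch] = len(mapping)
        out.append(mapping[ch])
    return tuple(out)


def dedup_by_ani_clusters(positions, msa: MsaSet, ani_threshold: float = 0.05):
    """Collapse redundant positions within near-identical sample clusters.

    Samples are single-linkage clustered at SNP distance <= ``ani_threshold``;
    within each cluster, positions inducing the same sample partition carry
    identical information, and only the one with the fewest gaps (earliest
    on ties) is kept.  The union of kept positions over clusters is returned
    in the original order.
    """
    if not positions:
        return []
    arr = msa.to_array()
    D = _pairwise_snp_distance(arr)
    clusters = [c for c in _single_linkage_clusters(D, ani_threshold) if len(c) >= 2]
    if not clusters:
        # only singleton clusters: no within-cluster pattern information
        return list(positions)
    gap_counts = {p: int((arr[:, p - 1] == "-").sum()) for p in positions}
    kept: set[int] = set()
    for idx in clusters:
        groups: dict[tuple, list[int]] = {}
        for p in positions:
            signature = _partition_signature(arr[idx, p - 1])
            groups.setdefault(signature, []).append(p)
        for dup in groups.values():
            best = min(dup, key=lambda p: (gap_counts[p], p))
            kept.add(best)
    return [p for p in positions if p in kept]


def one_hot_encode(msa: MsaSet, positions) -> StrainFeatureMatrix:
    """Expand each kept position into five binary features (A, C, G, T, gap).

    An N residue leaves all five features at 0 (missing data); otherwise
    exactly one of the five is 1 per (sample, position).
    """
    arr = msa.to_array()
    n = arr.shape[0]
    feats = []
    cols = []
    for p in positions:
        col = arr[:, p - 1]
        for sym, name in zip(SYMBOLS, SYMBOL_NAMES):
            feats.append((msa.sgb_id, int(p), name))
            cols.append((col == sym).astype(np.int8))
    values = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    return StrainFeatureMatrix(
        feature_ids=feats,
        sample_ids=list(msa.sample_ids),
        values=values,
        provenance={"funnel": [("one_hot", len(feats))]},
    )


def prevalence_filter(matrix: StrainFeatureMatrix, sample_mask=None,
                      low: float = 0.20, high: float = 0.80) -> StrainFeatureMatrix:
    """Keep features with pooled prevalence in [low, high] (inclusive).

    ``sample_mask`` restricts the prevalence computation to the pooled
    control+case samples when other conditions are present.
    """
    vals = matrix.values
    if sample_mask is not None:
        vals = vals[np.asarray(sample_mask, dtype=bool)]
    if vals.shape[0] == 0:
        raise ValueError("no samples for prevalence computation")
    prev = vals.mean(axis=0)
    keep = (prev >= low) & (prev <= high)
    return matrix.select(keep, f"prevalence[{low},{high}]")


def collinearity_prune(matrix: StrainFeatureMatrix, r_max: float = 0.5) -> StrainFeatureMatrix:
    """Greedy left-to-right pruning of correlated binary features.

    Feature i is kept iff |Pearson r| <= r_max against every previously kept
    feature (Pearson on 0/1 vectors is the phi coefficient).  Zero-variance
    features are dropped first with a warning.
    """
    X = matrix.values.astype(float)
    n, m = X.shape
    var = X.var(axis=0)
    constant = var == 0
    if constant.any():
        logger.warning("collinearity_prune: dropping %d constant features",
                       int(constant.sum()))
    keep_flags = np.zeros(m, dtype=bool)
    kept_idx: list[int] = []
    if n > 1:
        Xc = X - X.mean(axis=0)
        norms = np.sqrt((Xc**2).sum(axis=0))
        for i in range(m):
            if constant[i]:
                continue
            if kept_idx:
                r = (Xc[:, kept_idx].T @ Xc[:, i]) / (norms[kept_idx] * norms[i])
                if np.any(np.abs(r) > r_max):
                    continue
            keep_flags[i] = True
            kept_idx.append(i)
    return matrix.select(keep_flags, f"collinearity<=|{r_max}|")


def strain_feature_pipeline(msa: MsaSet, sample_mask=None, entropy_min: float = 0.5,
                            ani_dedup: bool = True, ani_threshold: float = 0.05,
                            prev_low: float = 0.20, prev_high: float = 0.80,
                            r_max: float = 0.5) -> StrainFeatureMatrix:
    """Full funnel: entropy selection -> dedup -> one-hot -> prevalence -> prune."""
    positions, _ = select_positions(msa, entropy_min=entropy_min)
    if ani_dedup:
        positions = dedup_by_ani_clusters(positions, msa, ani_threshold=ani_threshold)
    mat = one_hot_encode(msa, positions)
    logger.info("strain funnel %s: %d one-hot features", msa.sgb_id, mat.n_features)
    if mat.n_features == 0:
        return mat
    mat = prevalence_filter(mat, sample_mask=sample_mask, low=prev_low, high=prev_high)
    mat = collinearity_prune(mat, r_max=r_max)
    logger.info("strain funnel %s: %s", msa.sgb_id, mat.provenance.get("funnel"))
    return mat


def strain_permanova(matrix: StrainFeatureMatrix, labels, blocks=None,
                     n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Jaccard-distance blocked PERMANOVA on the binary strain features.

    Samples with an all-zero feature row are excluded (warned): they carry
    no presence information and make Jaccard undefined.
    """
    labels = np.asarray(labels)
    blocks_arr = None if blocks is None else np.asarray(blocks)
    nonzero = matrix.values.sum(axis=1) > 0
    if not nonzero.all():
        logger.warning("strain_permanova: excluding %d all-zero samples",
                       int((~nonzero).sum()))
    vals = matrix.values[nonzero]
    labels = labels[nonzero]
    if blocks_arr is not None:
        blocks_arr = blocks_arr[nonzero]
    D = jaccard_matrix(vals.astype(bool))
    return permanova_blocked(D, labels, blocks=blocks_arr, n_perm=n_perm, seed=seed)
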