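"""Oral-typical species signature derivation and oral-to-gut scoring.

An SGB is called oral-typical when, over participants sampled at both body
sites, it is (1) exclusively oral in at least 20% of participants,
(2) present in both sites in fewer participants than exclusively oral, and
(3) exclusively in stool in fewer than 5% of participants.  All three
fractions share the same denominator: the number of participants with both
samples.

The two downstream statistics on a stool profile are the oral-to-gut score
(summed relative abundance of signature members present) and oral-to-gut
richness (count of signature members detected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CrcMetaError, SignatureSet


@dataclass
class OralSignature:
    members: set[str]
    per_sgb_stats: dict[str, tuple[float, float, float]]  # (oral_only, both, stool_only)
    min_oral_only: float = 0.20
    max_stool_only: float = 0.05

    def __contains__(self, sgb: str) -> bool:
        return sgb in self.members

    def __len__(self) -> int:
        return len(self.members)

    def as_signature_set(self, name: str = "oral_typical") -> SignatureSet:
        return SignatureSet(name=name, members=set(self.members),
                            provenance="paired body-site prevalence criteria")


def derive_oral_signature(oral_presence: pd.DataFrame, stool_presence: pd.DataFrame,
                          min_oral_only: float = 0.20,
                          max_stool_only: float = 0.05) -> OralSignature:
    """Derive the oral-typical panel from paired presence tables.

    Both tables are participants x SGBs boolean/0-1 frames indexed by
    participant; only participants present in both tables (paired samples)
    count.  An SGB absent from one table is treated as absent at that site.
    """
    participants = oral_presence.index.intersection(stool_presence.index)
    if len(participants) == 0:
        raise CrcMetaError("no participants with both body sites")
    sgbs = oral_presence.columns.union(stool_presence.columns)
    oral = oral_presence.reindex(index=participants, columns=sgbs, fill_value=0).astype(bool)
    stool = stool_presence.reindex(index=participants, columns=sgbs, fill_value=0).astype(bool)
    n = len(participants)

    oral_only = (oral & ~stool).sum(axis=0) / n
    both = (oral & stool).sum(axis=0) / n
    stool_only = (~oral & stool).sum(axis=0) / n

    members = set(
        sgbs[(oral_only >= min_oral_only) & (both < oral_only) & (stool_only < max_stool_only)]
    )
    per_sgb = {
        s: (float(oral_only[s]), float(both[s]), float(stool_only[s])) for s in sgbs
    }
    return OralSignature(members=members, per_sgb_stats=per_sgb,
                         min_oral_only=min_oral_only, max_stool_only=max_stool_only)


def oral_to_gut_score(sample, feature_ids, signature) -> float:
    """Sum of relative abundances of signature members in a stool sample."""
    x = np.asarray(sample, dtype=float)
    members = signature.members if hasattr(signature, "members") else set(signature)
    mask = np.fromiter((f in members for f in feature_ids), dtype=bool, count=len(feature_ids))
    return float(x[mask].sum())


def oral_to_gut_richness(sample, feature_ids, signature, detection_threshold: float = 0.0) -> int:
    """Count of distinct signature members detected in a stool sample."""
    x = np.asarray(sample, dtype=float)
    members = signature.members if hasattr(signature, "members") else set(signature)
    mask = np.fromiter((f in members for f in feature_ids), dtype=bool, count=len(feature_ids))
    return int(np.sum(x[mask] > detection_threshold))


def enrichment_fisher(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table [[a, b], [c, d]].

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.  The
    sample odds ratio is (a d)/(b c), infinite when b c = 0 with a d > 0 and
    NaN (undefined) when a margin is zero.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        return math_or_nan(a, b, c, d), 1.0
    rv = stats.hypergeom(n, col1, row1)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    # tolerance guards against ties broken by floating point noise
    p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
    return math_or_nan(a, b, c, d), min(1.0, p)


def math_or_nan(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with the conventional infinities/NaN edge cases."""
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return float("nan")
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)
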