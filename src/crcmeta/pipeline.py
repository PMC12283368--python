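"""Orchestration: contrast grammar, run configuration and the end-to-end run.

A contrast spec is a string of the form ``"<field>:<level>[,<level>...] vs
<field>:<level>[,...]"`` over the metadata fields condition, stage and
location, e.g. ``"condition:CRC vs condition:control"`` or
``"stage:0,I,II vs stage:III,IV"``.  Stage/location contrasts silently
exclude samples whose stage or location is unknown.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diversity, ml, oral, signatures, simulate, strains
from .io import (
    CrcMetaError,
    SampleMetadata,
    metadata_frame,
    write_abundance_table,
    write_metadata,
)
from .meta import meta_analyse

logger = logging.getLogger(__name__)

_CONTRAST_FIELDS = {
    "condition": {"control", "adenoma", "CRC"},
    "stage": {"0", "I", "II", "III", "IV"},
    "location": {"right", "left"},
}


class ContrastError(CrcMetaError):
    pass


def _parse_side(side: str) -> tuple[str, set[str]]:
    side = side.strip()
    if ":" not in side:
        raise ContrastError(f"bad contrast side: {side!r}")
    fld, levels = side.split(":", 1)
    fld = fld.strip()
    if fld not in _CONTRAST_FIELDS:
        raise ContrastError(f"unknown contrast field: {fld!r}")
    vals = {v.strip() for v in levels.split(",") if v.strip()}
    bad = vals - _CONTRAST_FIELDS[fld]
    if bad:
        raise ContrastError(f"unknown {fld} levels: {sorted(bad)}")
    if not vals:
        raise ContrastError(f"no levels given for {fld}")
    return fld, vals


def define_contrast(metadata: list[SampleMetadata], spec: str):
    """Split samples into two disjoint sets per a contrast spec string.

    Returns (group1_ids, group2_ids): group 1 is the left side of ``vs``
    (the case/late/right side by the package's direction convention).
    """
    if " vs " not in spec:
        raise ContrastError(f"contrast must contain ' vs ': {spec!r}")
    left, right = spec.split(" vs ", 1)
    f1, v1 = _parse_side(left)
    f2, v2 = _parse_side(right)
    if f1 == f2 and v1 & v2:
        raise ContrastError(f"overlapping levels in contrast: {sorted(v1 & v2)}")

    def matches(m: SampleMetadata, fld: str, vals: set[str]) -> bool:
        value = {"condition": m.condition.value, "stage": m.stage.value,
                 "location": m.location.value}[fld]
        if fld in ("stage", "location") and value == "unknown":
            return False
        return value in vals

    g1 = [m.sample_id for m in metadata if matches(m, f1, v1)]
    g2 = [m.sample_id for m in metadata if matches(m, f2, v2)]
    overlap = set(g1) & set(g2)
    if overlap:
        raise ContrastError(f"contrast sides overlap on {len(overlap)} samples")
    return g1, g2


@dataclass
class RunConfig:
    """End-to-end synthetic-run configuration."""

    out_dir: str = "crcmeta_run"
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    contrast: str = "condition:CRC vs condition:control"
    n_permutations: int = 199
    classifier: ml.ClassifierConfig = field(default_factory=lambda: ml.LIGHT_CONFIG)
    n_bodysite_participants: int = 495
    msa_samples: int = 60
    msa_positions: int = 200


def run_all(config: RunConfig) -> dict:
    """Chain simulate -> oral signature -> meta-analysis -> PERMANOVA ->
    LODO evaluation -> strain features -> signature comparison.

    Writes per-stage artifacts under ``config.out_dir`` and returns (and
    writes) a machine-readable summary.  On a stage failure the partially
    written run directory is removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_all_inner(config, out)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _run_all_inner(config: RunConfig, out: Path) -> dict:
    summary: dict = {"seed": config.seed, "contrast": config.contrast}
    sim = config.simulation
    if sim is None:
        planted = {f"SGB{i + 1:05d}": 0.8 for i in range(51, 61)}
        sim = simulate.SimulationConfig(seed=config.seed, planted_effects=planted)
    else:
        sim.seed = config.seed

    profiles, metadata, truth = simulate.generate_multicohort(sim)
    for prof in profiles:
        write_abundance_table(prof, out / f"abundance_{prof.cohort_id}.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    summary["simulate"] = {
        "n_cohorts": len(profiles),
        "n_samples": sum(p.n_samples for p in profiles),
        "n_features": sim.n_features,
    }

    # oral signature from paired body sites
    bs_truth = simulate.default_bodysite_truth(
        n_sgbs=sim.n_features, n_oral_typical=sim.n_oral_features,
        seed=config.seed + 1,
    )
    oral_df, stool_df, true_sig = simulate.generate_paired_bodysites(
        config.n_bodysite_participants, bs_truth, seed=config.seed + 2,
    )
    sig = oral.derive_oral_signature(oral_df, stool_df)
    tp = len(sig.members & true_sig.members)
    summary["oral_signature"] = {
        "n_members": len(sig.members),
        "recall": tp / len(true_sig.members) if true_sig.members else float("nan"),
        "precision": tp / len(sig.members) if sig.members else float("nan"),
    }

    # meta-analysis on the contrast
    g1, g2 = define_contrast(metadata, config.contrast)
    group_of = {s: 1 for s in g1}
    group_of.update({s: 0 for s in g2})
    records = meta_analyse(profiles, lambda s: group_of.get(s))
    import csv

    with open(out / "meta_analysis.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["feature_id", "k", "g_pooled", "ci_low", "ci_high",
                    "tau2", "i2", "p", "q"])
        for r in sorted(records, key=lambda r: r.q):
            w.writerow([r.feature_id, r.k, f"{r.g_pooled:.6g}", f"{r.ci_low:.6g}",
                        f"{r.ci_high:.6g}", f"{r.tau2:.6g}", f"{r.i2:.4g}",
                        f"{r.p:.6g}", f"{r.q:.6g}"])
    summary["meta_analysis"] = {
        "n_features_tested": len(records),
        "n_significant_q10": int(sum(r.q < 0.1 for r in records)),
    }

    # blocked PERMANOVA on Bray-Curtis
    mdf = metadata_frame(metadata)
    in_contrast = [s for s in mdf.index if s in group_of]
    X, labels, blocks = [], [], []
    for prof in profiles:
        keep = [j for j, s in enumerate(prof.sample_ids) if s in group_of]
        X.append(prof.abundances[:, keep].T)
        labels += [group_of[prof.sample_ids[j]] for j in keep]
        blocks += [prof.cohort_id] * len(keep)
    Xall = np.vstack(X)
    D = diversity.bray_curtis_matrix(Xall)
    perma = diversity.permanova_blocked(
        D, labels, blocks=blocks, n_perm=config.n_permutations, seed=config.seed + 3,
    )
    summary["permanova"] = {"r2": perma.r2, "pseudo_f": perma.pseudo_f,
                            "p": perma.p, "n_perm": perma.n_perm}

    # LODO evaluation
    cohort_data = {}
    for prof in profiles:
        keep = [s for s in prof.sample_ids if s in group_of]
        sub = prof.subset_samples(keep)
        cohort_data[prof.cohort_id] = (
            ml.prepare_features(sub, "all"),
            np.array([group_of[s] for s in keep]),
        )
    lodo_aucs = ml.evaluate_all(cohort_data, mode="lodo",
                                classifier_config=config.classifier,
                                seed=config.seed + 4)
    summary["lodo"] = {
        cid: (None if a is None else round(float(a), 4)) for cid, a in lodo_aucs.items()
    }

    # strain features from a clade-structured MSA aligned with labels
    n_msa = min(config.msa_samples, len(in_contrast))
    g1_in = [s for s in in_contrast if group_of[s] == 1][: n_msa // 2]
    g2_in = [s for s in in_contrast if group_of[s] == 0][: n_msa - n_msa // 2]
    # interleave the two groups so round-robin clade assignment aligns
    # clade pairs with the contrast (the planted-association scenario)
    msa_samples = [s for pair in zip(g1_in, g2_in) for s in pair]
    n_msa = len(msa_samples)
    msa, _msa_truth = simulate.generate_msa(
        n_msa, config.msa_positions, n_clades=4,
        divergence=0.01, gap_rate=0.02,
        seed=config.seed + 5,
    )
    mat = strains.strain_feature_pipeline(msa)
    msa_labels = [group_of[s] for s in msa_samples]
    summary["strain_features"] = {"funnel": mat.provenance.get("funnel", [])}
    if mat.n_features >= 2:
        res = strains.strain_permanova(
            mat, msa_labels[: len(mat.sample_ids)],
            n_perm=config.n_permutations, seed=config.seed + 6,
        )
        summary["strain_features"]["permanova_p"] = res.p
        summary["strain_features"]["permanova_r2"] = res.r2

    # signature comparison: significant features vs true oral panel
    sig_hits = {r.feature_id for r in records if r.q < 0.1 and r.g_pooled > 0}
    oral_members = set(truth["oral_features"])
    summary["signature_compare"] = {
        "n_crc_associated": len(sig_hits),
        "jaccard_vs_oral": signatures.jaccard_similarity(sig_hits, oral_members),
        "overlap_with_oral": (
            signatures.overlap_fraction(sig_hits, oral_members) if sig_hits else None
        ),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
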