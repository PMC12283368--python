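"""Synthetic multi-cohort stool-metagenome data with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: per-cohort compositional relative-abundance tables with log-normal
marginals, cohort batch effects as per-feature log-scale offsets, planted
case-control standardized mean differences, elevated oral-species
introgression in cases, monotone stage trends, and clade-structured
marker-gene alignments.  A fixed seed yields bit-identical output.

Effect calibration (closed form).  Planted effects are targets on the
Hedges'-g scale of arcsine-sqrt-transformed abundances.  For a low-abundance
feature with within-class log-abundance standard deviation sigma, the
transformed value is approximately sqrt(p) = exp(log p / 2), i.e. lognormal
with log-sd sigma/2.  Shifting the case log-abundance by delta then gives a
standardized mean difference of

    g(delta) = (e^{delta/2} - 1)
               / ( sqrt(e^{sigma^2/4} - 1) * sqrt((1 + e^{delta}) / 2) )

(mean ratio minus one over the pooled lognormal coefficient of variation).
The generator inverts this monotone mapping per feature by bisection to find
the delta achieving each target g.  The mapping saturates at
g_max = sqrt(2) / sqrt(e^{sigma^2/4} - 1); targets beyond 98% of g_max are
capped (class separation keeps growing with delta, but the realized g
plateaus).  Compositional closure is compensated separately (see
generate_multicohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CohortProfile,
    Condition,
    CrcMetaError,
    Location,
    MsaSet,
    SampleMetadata,
    Sex,
    SignatureSet,
    Stage,
)

_STAGES = [Stage.S0, Stage.SI, Stage.SII, Stage.SIII, Stage.SIV]
# stage mix close to the multi-cohort corpus the framework targets
_STAGE_PROBS = np.array([94, 253, 257, 286, 301], dtype=float)
_STAGE_PROBS /= _STAGE_PROBS.sum()
_LOCATION_P_RIGHT = 344 / (344 + 645)


class ConfigError(CrcMetaError):
    pass


def _asin_sqrt_delta(g_target, sigma) -> np.ndarray:
    """Log-scale case shift achieving a target asin-sqrt-scale Hedges' g.

    Inverts the module-level calibration formula by vectorized bisection;
    antisymmetric in the sign of the target.  Targets above 98% of the
    mapping's saturation value are capped.
    """
    g_target = np.atleast_1d(np.asarray(g_target, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), g_target.shape)
    a = np.sqrt(np.exp(sigma**2 / 4.0) - 1.0)
    g_max = np.sqrt(2.0) / a
    target = np.minimum(np.abs(g_target), 0.98 * g_max)

    def g_of(delta):
        return (np.expm1(delta / 2.0)) / (a * np.sqrt((1.0 + np.exp(delta)) / 2.0))

    lo = np.zeros_like(target)
    hi = np.full_like(target, 60.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        too_small = g_of(mid) < target
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    delta = 0.5 * (lo + hi)
    delta[target == 0.0] = 0.0
    return np.sign(g_target) * delta


@dataclass
class SimulationConfig:
    """Study conditions for the multi-cohort generator."""

    n_cohorts: int = 5
    samples_per_class: dict = field(
        default_factory=lambda: {"control": 100, "CRC": 100}
    )
    n_features: int = 300
    n_oral_features: int = 50
    planted_effects: dict = field(default_factory=dict)  # feature_id -> target g
    oral_introgression_boost: float = 3.0  # x-fold latent abundance in CRC
    stage_trend_features: set = field(default_factory=set)
    stage_trend_g: float = 0.6  # asin-sqrt g between stage 0 and stage IV
    cohort_batch_sd: float = 0.5
    base_log_mean_sd: float = 1.5
    log_noise_sd_range: tuple = (0.6, 1.4)
    prevalence_range: tuple = (0.6, 1.0)  # non-oral features
    oral_prevalence_range: tuple = (0.25, 0.6)  # oral features, in controls
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts <= 0 or self.n_features <= 0:
            raise ConfigError("counts must be positive")
        if self.n_oral_features > self.n_features:
            raise ConfigError("n_oral_features exceeds n_features")
        if any(n < 0 for n in self.samples_per_class.values()):
            raise ConfigError("negative class size")
        unknown = set(self.planted_effects) - set(self.feature_ids())
        if unknown:
            raise ConfigError(f"planted effects for unknown features: {sorted(unknown)[:5]}")
        unknown = set(self.stage_trend_features) - set(self.feature_ids())
        if unknown:
            raise ConfigError(f"stage trends for unknown features: {sorted(unknown)[:5]}")

    def feature_ids(self) -> list[str]:
        return [f"SGB{i + 1:05d}" for i in range(self.n_features)]

    def oral_feature_ids(self) -> list[str]:
        return self.feature_ids()[: self.n_oral_features]


def generate_multicohort(config: SimulationConfig):
    """Generate (profiles, metadata, ground_truth) per the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    feature_ids = config.feature_ids()
    oral_set = set(config.oral_feature_ids())
    F = config.n_features

    # feature-level parameters shared across cohorts
    mu = rng.normal(0.0, config.base_log_mean_sd, size=F)
    sigma = rng.uniform(*config.log_noise_sd_range, size=F)
    prevalence = rng.uniform(*config.prevalence_range, size=F)
    is_oral = np.array([f in oral_set for f in feature_ids])
    prevalence[is_oral] = rng.uniform(*config.oral_prevalence_range, size=is_oral.sum())
    # oral species are rarer in stool: push their latent mean down
    mu[is_oral] -= 2.0

    g_target = np.array([config.planted_effects.get(f, 0.0) for f in feature_ids])
    # planted features keep near-full prevalence so the target g is realized
    prevalence[g_target != 0.0] = np.maximum(prevalence[g_target != 0.0], 0.98)
    trend_mask = np.array([f in config.stage_trend_features for f in feature_ids])
    log_boost = np.log(config.oral_introgression_boost)

    profiles: list[CohortProfile] = []
    metadata: list[SampleMetadata] = []
    for c in range(config.n_cohorts):
        cohort_id = f"cohort{c + 1:02d}"
        batch = rng.normal(0.0, config.cohort_batch_sd, size=F)
        sample_ids: list[str] = []
        conditions: list[str] = []
        stages: list[Stage] = []
        for cls, n_cls in sorted(config.samples_per_class.items()):
            for i in range(n_cls):
                sid = f"{cohort_id}_{cls}_{i + 1:04d}"
                sample_ids.append(sid)
                conditions.append(cls)
                if cls == "CRC":
                    stages.append(_STAGES[rng.choice(5, p=_STAGE_PROBS)])
                else:
                    stages.append(Stage.UNKNOWN)
        n = len(sample_ids)
        if n == 0:
            raise ConfigError("cohort with zero samples")

        logab = (
            mu[:, None]
            + batch[:, None]
            + sigma[:, None] * rng.standard_normal((F, n))
        )
        stage_frac = np.array(
            [(_STAGES.index(s) / 4.0) if s is not Stage.UNKNOWN else 0.0 for s in stages]
        )
        is_case = np.array([cond == "CRC" for cond in conditions], dtype=float)
        # planted case effects, on the calibrated log scale
        shift = _asin_sqrt_delta(g_target, sigma)[:, None] * is_case[None, :]
        # oral introgression: multiplicative latent boost in cases
        shift += np.where(is_oral, log_boost, 0.0)[:, None] * is_case[None, :]
        # monotone stage gradients
        trend_delta = _asin_sqrt_delta(
            np.where(trend_mask, config.stage_trend_g, 0.0), sigma
        )
        shift += trend_delta[:, None] * stage_frac[None, :]
        # Closure compensation: planted shifts inflate a case sample's latent
        # total, and after closure that depresses every feature of the sample,
        # attenuating the planted effects.  Inflate the shifted features by
        # the expected log-total inflation (lognormal means as weights, short
        # fixed-point iteration) so the realized post-closure shift of each
        # planted feature tracks its target.  Unshifted features keep a small
        # residual negative offset in case samples — the unavoidable
        # compositional counterpart of the planted mass.
        w = np.exp(mu + batch + sigma**2 / 2.0)
        nonzero = shift != 0.0
        corr = np.zeros(n)
        for _ in range(5):
            s = shift + corr[None, :] * nonzero
            corr = np.log((w[:, None] * np.exp(s)).sum(axis=0) / w.sum())
        logab += shift + corr[None, :] * nonzero

        ab = np.exp(logab)
        ab /= ab.sum(axis=0, keepdims=True)  # compositional closure

        # zero-inflation: per feature, zero out the smallest values so that
        # the realized prevalence matches the configured target
        for i in range(F):
            n_zero = int(round(n * (1.0 - prevalence[i])))
            if n_zero > 0:
                cut = np.argsort(ab[i], kind="stable")[:n_zero]
                ab[i, cut] = 0.0

        profiles.append(
            CohortProfile(
                cohort_id=cohort_id,
                feature_ids=list(feature_ids),
                sample_ids=sample_ids,
                abundances=ab,
            )
        )
        for sid, cond, stage in zip(sample_ids, conditions, stages):
            is_crc = cond == "CRC"
            location = Location.UNKNOWN
            if is_crc:
                location = (
                    Location.RIGHT
                    if rng.random() < _LOCATION_P_RIGHT
                    else Location.LEFT
                )
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    cohort_id=cohort_id,
                    condition=Condition(cond),
                    stage=stage if is_crc else Stage.UNKNOWN,
                    location=location,
                    age=float(np.round(rng.normal(60.0, 10.0), 1)),
                    sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                    bmi=float(np.round(rng.normal(26.0, 4.0), 1)),
                    primary_tumor_in_situ="yes" if is_crc else "not_applicable",
                )
            )

    ground_truth = {
        "planted_g": dict(config.planted_effects),
        "oral_features": sorted(oral_set),
        "stage_trend_features": sorted(config.stage_trend_features),
        "prevalence": {f: float(p) for f, p in zip(feature_ids, prevalence)},
        "seed": config.seed,
    }
    return profiles, metadata, ground_truth


# ---------------------------------------------------------------------------
# paired body-site presence data
# ---------------------------------------------------------------------------

def default_bodysite_truth(n_sgbs: int = 300, n_oral_typical: int = 60,
                           seed: int = 0) -> dict:
    """Per-SGB (oral_only, both, stool_only) probabilities mimicking a
    healthy paired-sample population.

    The non-oral remainder mixes SGBs that fail each criterion: low oral
    prevalence, shared carriage exceeding exclusive-oral carriage (species
    genuinely colonizing both sites are typically found in both far more
    often than exclusively orally), oral species with substantial stool
    spill-over, and gut-only commensals.
    """
    rng = np.random.default_rng(seed)
    truth: dict[str, tuple[float, float, float]] = {}
    ids = [f"SGB{i + 1:05d}" for i in range(n_sgbs)]
    rest = ids[n_oral_typical:]
    quarters = np.array_split(np.arange(len(rest)), 4)
    for sgb in ids[:n_oral_typical]:
        po = rng.uniform(0.25, 0.6)
        pb = rng.uniform(0.0, 0.5) * po
        ps = rng.uniform(0.0, 0.03)
        truth[sgb] = (po, pb, ps)
    for qi, idxs in enumerate(quarters):
        for j in idxs:
            sgb = rest[j]
            if qi == 0:  # fails criterion 1: rarely oral at all
                po = rng.uniform(0.0, 0.15)
                truth[sgb] = (po, rng.uniform(0.0, 0.1), rng.uniform(0.0, 0.03))
            elif qi == 1:  # fails criterion 2: shared carriage dominates
                po = rng.uniform(0.2, 0.4)
                pb = min(po * rng.uniform(1.5, 3.0), 0.95 - po)
                truth[sgb] = (po, pb, rng.uniform(0.0, 0.03))
            elif qi == 2:  # fails criterion 3: substantial stool spill-over
                po = rng.uniform(0.25, 0.5)
                truth[sgb] = (po, rng.uniform(0.0, 0.3) * po, rng.uniform(0.08, 0.3))
            else:  # gut-only commensal
                truth[sgb] = (0.0, rng.uniform(0.0, 0.02), rng.uniform(0.2, 0.9))
    return truth


def true_oral_members(truth: dict, min_oral_only: float = 0.20,
                      max_stool_only: float = 0.05) -> set[str]:
    """SGBs whose TRUE probabilities satisfy the three signature criteria."""
    return {
        sgb
        for sgb, (po, pb, ps) in truth.items()
        if po >= min_oral_only and pb < po and ps < max_stool_only
    }


def generate_paired_bodysites(n_participants: int, truth: dict, seed: int = 0):
    """Bernoulli body-site presence draws per participant and SGB.

    Returns (oral_presence, stool_presence, true_signature): two boolean
    participants x SGBs DataFrames plus the SGBs whose true probabilities
    satisfy the signature criteria.
    """
    if n_participants <= 0:
        raise ConfigError("n_participants must be positive")
    for sgb, (po, pb, ps) in truth.items():
        if min(po, pb, ps) < 0 or po + pb + ps > 1 + 1e-12:
            raise ConfigError(f"invalid probability triple for {sgb}")
    rng = np.random.default_rng(seed)
    sgbs = list(truth)
    participants = [f"P{i + 1:04d}" for i in range(n_participants)]
    oral = np.zeros((n_participants, len(sgbs)), dtype=bool)
    stool = np.zeros((n_participants, len(sgbs)), dtype=bool)
    for j, sgb in enumerate(sgbs):
        po, pb, ps = truth[sgb]
        u = rng.random(n_participants)
        oral_only = u < po
        both = (u >= po) & (u < po + pb)
        stool_only = (u >= po + pb) & (u < po + pb + ps)
        oral[:, j] = oral_only | both
        stool[:, j] = stool_only | both
    oral_df = pd.DataFrame(oral, index=participants, columns=sgbs)
    stool_df = pd.DataFrame(stool, index=participants, columns=sgbs)
    sig = SignatureSet(
        name="true_oral", members=true_oral_members(truth),
        provenance="generator ground truth",
    )
    return oral_df, stool_df, sig


# ---------------------------------------------------------------------------
# clade-structured marker-gene alignments
# ---------------------------------------------------------------------------

def generate_msa(n_samples: int, n_positions: int, n_clades: int = 2,
                 clade_assignments: dict | None = None,
                 divergence: float = 0.01, gap_rate: float = 0.02,
                 n_discriminating: int | None = None,
                 seed: int = 0, sgb_id: str = "SGB_sim"):
    """Simulate an aligned marker-gene MSA with planted clade structure.

    Each clade has a consensus differing from the root at a known set of
    discriminating positions; samples copy their clade consensus, then each
    position mutates with probability ``divergence`` and gaps appear with
    probability ``gap_rate``.  Returns (MsaSet, truth) where truth carries
    the clade assignment per sample and the discriminating positions
    (1-based).
    """
    if n_samples <= 0 or n_positions <= 0 or n_clades <= 0:
        raise ConfigError("counts must be positive")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=n_positions)
    if n_discriminating is None:
        n_discriminating = max(1, n_positions // 10) if n_clades > 1 else 0
    disc = (
        np.sort(rng.choice(n_positions, size=min(n_discriminating, n_positions),
                           replace=False))
        if n_discriminating
        else np.array([], dtype=int)
    )
    consensus = np.tile(root, (n_clades, 1))
    for k in range(1, n_clades):
        for pos in disc:
            consensus[k, pos] = (root[pos] + k) % 4

    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    if clade_assignments is None:
        clades = {s: i % n_clades for i, s in enumerate(sample_ids)}
    else:
        clades = {s: clade_assignments[s] for s in sample_ids}

    sequences = []
    for s in sample_ids:
        seq = consensus[clades[s]].copy()
        if divergence > 0:
            mut = rng.random(n_positions) < divergence
            shift = rng.integers(1, 4, size=n_positions)
            seq = np.where(mut, (seq + shift) % 4, seq)
        chars = bases[seq]
        if gap_rate > 0:
            gaps = rng.random(n_positions) < gap_rate
            chars = np.where(gaps, "-", chars)
        sequences.append("".join(chars))

    msa = MsaSet(sgb_id=sgb_id, sample_ids=sample_ids, sequences=sequences)
    truth = {
        "clade_of": dict(clades),
        "discriminating_positions": [int(p) + 1 for p in disc],
        "seed": seed,
    }
    return msa, truth
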