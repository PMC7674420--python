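"""Synthetic crossover-trial cohorts with planted predictive effects.

The generator mirrors the structure of a two-trial dietary crossover study:
each participant belongs to one trial (whole-grain or low-gluten), completes
two 8-week periods (intervention and refined-grain control, order
randomized) and contributes one observation per period.  Responder status
is drawn first from a logistic model over diet arm plus a participant
random intercept; the relative weight change is then drawn from a
class-specific truncated Gaussian whose *truncated* moments match the
configured responder / non-responder means and SDs, so sign always agrees
with the class and class-conditional means converge to the configured
values.

Omics-like feature blocks (clinical, 16S, metabolome, genotype, GRS) are
generated at reduced scale; "planted" features are shifted in responders by
a configured effect (in SD units), making them recoverable by the
downstream models.  Block-wise whole-sample missingness yields a
complete-case subset, as in real multi-assay cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import omics
from .postprandial import BLOOD_TIMES_MIN, BREATH_TIMES_MIN

logger = logging.getLogger(__name__)

ARMS = ("whole_grain", "low_gluten", "refined")
BLOOD_MARKERS = ("glucose", "insulin", "ffa", "glp2")
BREATH_MARKER = "breath_h2"

# smooth postprandial template: (baseline level, excursion amplitude, peak minute, noise sd)
_MARKER_SHAPES = {
    "glucose": (5.0, 2.5, 45.0, 0.25),
    "insulin": (40.0, 160.0, 40.0, 8.0),
    "ffa": (0.5, -0.3, 90.0, 0.03),
    "glp2": (15.0, 10.0, 60.0, 1.0),
    BREATH_MARKER: (10.0, 25.0, 150.0, 2.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic cohort generator."""

    n_participants: int = 102
    arms: tuple[str, ...] = ARMS
    responder_mean_pct: float = -1.67
    responder_sd_pct: float = 1.42
    nonresponder_mean_pct: float = 1.39
    nonresponder_sd_pct: float = 1.2
    diet_effect: dict = field(
        default_factory=lambda: {"whole_grain": 0.35, "low_gluten": 0.35, "refined": -0.35}
    )
    planted_features: tuple = ()  # (block, feature, effect in SD units) triples
    missingness: dict = field(default_factory=dict)  # block label -> sample-drop fraction
    participant_intercept_sd: float = 0.5
    postprandial_volatility_effect: float = 0.5
    postprandial_missing_one_frac: float = 0.05
    postprandial_missing_many_frac: float = 0.02
    n_missing_weight: int = 1
    n_clinical: int = 8
    n_otus: int = 200
    n_metabolites: int = 100
    n_snps: int = 500
    n_grs: int = 5
    ld_block_size: int = 10
    ld_rho: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not self.arms:
            raise ValueError("arms must be nonempty")
        if self.responder_sd_pct <= 0 or self.nonresponder_sd_pct <= 0:
            raise ValueError("sd values must be > 0")
        for frac in self.missingness.values():
            if not 0 <= frac < 1:
                raise ValueError("missingness fractions must be in [0, 1)")
        if not 0 <= self.postprandial_missing_one_frac <= 1:
            raise ValueError("missing fractions must be in [0, 1]")


def _match_truncnorm(target_mean: float, target_sd: float, lower: float, upper: float):
    """Find (mu, sigma) of a truncated normal whose truncated moments match.

    Ensures the class-conditional weight-change distribution both respects
    the sign constraint and converges to the configured mean/SD.
    """

    def residual(p):
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - target_mean, float(np.sqrt(v)) - target_sd]

    sol, info, ier, msg = optimize.fsolve(
        residual, x0=[target_mean, np.log(target_sd)], full_output=True
    )
    if ier != 1:
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def draw_delta_w_pct(config: SynthConfig, responder: bool, n: int, rng: np.random.Generator):
    """Class-conditional relative weight changes in percent (sign-consistent)."""
    if responder:
        mu, sigma = _match_truncnorm(config.responder_mean_pct, config.responder_sd_pct, -np.inf, 0.0)
        a, b = -np.inf, (0.0 - mu) / sigma
    else:
        mu, sigma = _match_truncnorm(config.nonresponder_mean_pct, config.nonresponder_sd_pct, 0.0, np.inf)
        a, b = (0.0 - mu) / sigma, np.inf
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the crossover cohort and its ground-truth labels.

    Returns ``(cohort, truth)``.  The cohort table has one row per
    (participant, period) with columns sample_id, participant_id, period,
    diet_arm, w_before, w_after, age, sex, randomisation_order.  The truth
    table (never read by the pipeline) records the responder class, the
    responder probability and the participant intercept.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    rows, truth_rows = [], []
    ages = rng.normal(50, 8, n).clip(25, 70)
    sexes = rng.integers(0, 2, n)
    base_weights = rng.normal(85, 12, n).clip(50, 140)
    intercepts = rng.normal(0.0, config.participant_intercept_sd, n)
    orders = rng.integers(0, 2, n)
    trunc_params = {
        True: _match_truncnorm(config.responder_mean_pct, config.responder_sd_pct, -np.inf, 0.0),
        False: _match_truncnorm(config.nonresponder_mean_pct, config.nonresponder_sd_pct, 0.0, np.inf),
    }
    for i in range(n):
        trial_arm = "whole_grain" if i % 2 == 0 else "low_gluten"
        arm_order = (trial_arm, "refined") if orders[i] == 0 else ("refined", trial_arm)
        w_before = float(base_weights[i])
        for period, arm in enumerate(arm_order, start=1):
            sid = f"P{i:04d}_V{period}"
            logit = config.diet_effect.get(arm, 0.0) + intercepts[i]
            p_resp = float(_sigmoid(logit))
            responder = bool(rng.random() < p_resp)
            mu, sigma = trunc_params[responder]
            if responder:
                a, b = -np.inf, (0.0 - mu) / sigma
            else:
                a, b = (0.0 - mu) / sigma, np.inf
            pct = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))
            delta_w = pct / 100.0
            w_after = w_before * (1.0 + delta_w)
            rows.append(
                {
                    "sample_id": sid,
                    "participant_id": f"P{i:04d}",
                    "period": period,
                    "diet_arm": arm,
                    "w_before": round(w_before, 3),
                    "w_after": round(w_after, 3),
                    "age": round(float(ages[i]), 1),
                    "sex": int(sexes[i]),
                    "randomisation_order": int(orders[i]),
                }
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "responder": int(responder),
                    "p_responder": p_resp,
                    "participant_intercept": float(intercepts[i]),
                }
            )
            # carry a little weight drift into the second baseline
            w_before = float(w_after + rng.normal(0.0, 0.4))
    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    # exercise the missing-weight exclusion path
    for j in range(min(config.n_missing_weight, len(cohort))):
        cohort.loc[cohort.index[-(j + 1)], "w_after"] = np.nan
    return cohort, truth


# ---------------------------------------------------------------------------
# Feature blocks
# ---------------------------------------------------------------------------

@dataclass
class FeatureBlock:
    """Named sample x feature matrix; missing samples are simply absent rows."""

    label: str
    data: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


def _planted_by_block(config: SynthConfig) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for block, feature, effect in config.planted_features:
        out.setdefault(block, {})[feature] = float(effect)
    return out


def _apply_planted(values: pd.DataFrame, planted: dict[str, float], responder: np.ndarray) -> None:
    for feature, effect in planted.items():
        sd = float(values[feature].std(ddof=0)) or 1.0
        values.loc[responder.astype(bool), feature] += effect * sd


def simulate_genotypes(
    config: SynthConfig, participant_ids: list[str], rng: np.random.Generator, mafs=None
) -> tuple[pd.DataFrame, pd.Series]:
    """Participant-level dosage matrix with LD blocks via a Gaussian copula.

    Within each LD block, haplotype latents share pairwise correlation
    ``ld_rho``; marginally every SNP is Binomial(2, MAF) so Hardy-Weinberg
    proportions hold.  ``ld_rho = 1`` duplicates columns exactly.
    """
    n = len(participant_ids)
    p = config.n_snps
    mafs = rng.uniform(0.05, 0.5, p) if mafs is None else np.broadcast_to(np.asarray(mafs, dtype=float), (p,))
    dosages = np.zeros((n, p), dtype=int)
    block = max(1, config.ld_block_size)
    rho = float(np.clip(config.ld_rho, 0.0, 1.0))
    for start in range(0, p, block):
        k = min(block, p - start)
        if rho > 0:
            shared1 = rng.normal(size=n)
            shared2 = rng.normal(size=n)
            noise1 = rng.normal(size=(n, k))
            noise2 = rng.normal(size=(n, k))
            h1 = np.sqrt(rho) * shared1[:, None] + np.sqrt(1 - rho) * noise1
            h2 = np.sqrt(rho) * shared2[:, None] + np.sqrt(1 - rho) * noise2
        else:
            h1 = rng.normal(size=(n, k))
            h2 = rng.normal(size=(n, k))
        thresh = stats.norm.ppf(mafs[start:start + k])
        dosages[:, start:start + k] = (h1 < thresh).astype(int) + (h2 < thresh).astype(int)
    cols = [f"snp_{j:04d}" for j in range(p)]
    geno = pd.DataFrame(dosages, index=participant_ids, columns=cols)
    positions = pd.Series(1000 * (np.arange(p) + 1), index=cols)
    return geno, positions


def simulate_omics_blocks(
    config: SynthConfig, cohort: pd.DataFrame, truth: pd.DataFrame | None = None
) -> dict[str, FeatureBlock]:
    """Generate all per-observation feature blocks for a cohort.

    Planted features (validated against the block vocabularies) are shifted
    in responder observations by their configured effect in SD units, which
    requires the ground-truth table; with ``truth=None`` planted effects
    must be empty.
    """
    rng = np.random.default_rng(config.seed + 1)
    planted = _planted_by_block(config)
    if planted and truth is None:
        raise ValueError("planted features require the ground-truth table")
    sample_ids = list(cohort["sample_id"])
    participants = list(cohort["participant_id"])
    uniq_participants = list(dict.fromkeys(participants))
    responder = (
        truth.set_index("sample_id").loc[sample_ids, "responder"].to_numpy()
        if truth is not None
        else np.zeros(len(sample_ids), dtype=int)
    )

    blocks: dict[str, FeatureBlock] = {}

    # Diet: one-hot triple
    diet = pd.get_dummies(cohort.set_index("sample_id")["diet_arm"], prefix="diet").astype(int)
    for arm in config.arms:
        col = f"diet_{arm}"
        if col not in diet.columns:
            diet[col] = 0
    diet = diet[[f"diet_{arm}" for arm in config.arms]]
    blocks["Diet"] = FeatureBlock("Diet", diet)

    def participant_base(n_features: int, scale: float = 1.0) -> np.ndarray:
        base = rng.normal(0.0, scale, (len(uniq_participants), n_features))
        idx = [uniq_participants.index(pid) for pid in participants]
        return base[idx]

    # ClinicalA: Gaussian anthropometric/physiology-like features
    clin_names = [f"clin_{j:02d}" for j in range(config.n_clinical)]
    clin = pd.DataFrame(
        participant_base(config.n_clinical) * 0.7 + rng.normal(0, 0.7, (len(sample_ids), config.n_clinical)),
        index=sample_ids,
        columns=clin_names,
    )
    _apply_planted(clin, planted.pop("ClinicalA", {}), responder)
    blocks["ClinicalA"] = FeatureBlock("ClinicalA", clin)

    # 16S: log-normal counts -> relative abundances; planted shift on log scale
    otu_names = [f"otu_{j:04d}" for j in range(config.n_otus)]
    log_mu = rng.normal(0.0, 2.0, config.n_otus)
    log_counts = (
        log_mu[None, :]
        + participant_base(config.n_otus, 0.6)
        + rng.normal(0, 0.8, (len(sample_ids), config.n_otus))
    )
    log_frame = pd.DataFrame(log_counts, index=sample_ids, columns=otu_names)
    _apply_planted(log_frame, planted.pop("16S_B", {}), responder)
    counts = np.exp(log_frame)
    # sparsify so prevalence filtering is meaningful
    zero_mask = rng.random(counts.shape) < 0.2
    counts = counts.mask(zero_mask, 0.0)
    rel = omics.relative_abundance_16s(counts)
    blocks["16S_B"] = FeatureBlock("16S_B", rel.fillna(0.0))

    # LC-MS: log-normal metabolite intensities
    met_names = [f"met_{j:04d}" for j in range(config.n_metabolites)]
    met = pd.DataFrame(
        participant_base(config.n_metabolites, 0.6)
        + rng.normal(0, 0.8, (len(sample_ids), config.n_metabolites)),
        index=sample_ids,
        columns=met_names,
    )
    _apply_planted(met, planted.pop("LC-MS", {}), responder)
    blocks["LC-MS"] = FeatureBlock("LC-MS", np.exp(met))

    # Genotype (participant-level, repeated across periods) and GRS
    geno_part, positions = simulate_genotypes(config, uniq_participants, rng)
    geno = geno_part.loc[participants].set_axis(sample_ids)
    geno_planted = planted.pop("Genotype", {})
    for feature, effect in geno_planted.items():
        if feature not in geno.columns:
            raise ValueError(f"planted feature {feature!r} not in Genotype block")
        maf_shift = np.clip(0.3 + 0.15 * effect, 0.01, 0.99)
        resp_idx = responder.astype(bool)
        geno.loc[resp_idx, feature] = rng.binomial(2, maf_shift, int(resp_idx.sum()))
    blocks["Genotype"] = FeatureBlock("Genotype", geno)
    blocks["Genotype"].data.attrs["positions"] = positions.to_dict()

    grs_cols = {}
    for g in range(config.n_grs):
        snps = rng.choice(geno.columns, size=int(rng.integers(4, 11)), replace=False)
        weights = {s: float(rng.normal(0, 0.3)) for s in snps}
        grs_cols[f"grs_{g}"] = omics.grs(geno, omics.GRSDefinition(weights))
    grs_frame = pd.DataFrame(grs_cols, index=sample_ids)
    _apply_planted(grs_frame, planted.pop("GRS", {}), responder)
    blocks["GRS"] = FeatureBlock("GRS", grs_frame)

    if planted:
        raise ValueError(f"planted features reference unknown blocks: {sorted(planted)}")
    return blocks


def simulate_postprandial(
    config: SynthConfig, cohort: pd.DataFrame, truth: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-format postprandial series per observation.

    Four blood markers at five time points (0-180 min) and breath H2 at
    eight half-hourly points.  Responders get extra point-to-point noise
    scaled by ``postprandial_volatility_effect``.  Per series, one missing
    point is injected with probability ``postprandial_missing_one_frac`` and
    two missing points with ``postprandial_missing_many_frac``.
    """
    rng = np.random.default_rng(config.seed + 2)
    sample_ids = list(cohort["sample_id"])
    responder = (
        truth.set_index("sample_id").loc[sample_ids, "responder"].to_numpy()
        if truth is not None
        else np.zeros(len(sample_ids), dtype=int)
    )
    rows = []
    for sid, is_resp in zip(sample_ids, responder):
        vol = 1.0 + config.postprandial_volatility_effect * is_resp
        for marker in (*BLOOD_MARKERS, BREATH_MARKER):
            times = BREATH_TIMES_MIN if marker == BREATH_MARKER else BLOOD_TIMES_MIN
            base, amp, peak, noise = _MARKER_SHAPES[marker]
            indiv_amp = amp * float(rng.lognormal(0.0, 0.2))
            t = np.asarray(times)
            curve = base + indiv_amp * (t / peak) * np.exp(1 - t / peak)
            values = curve + rng.normal(0.0, noise * vol, len(t))
            u = rng.random()
            if u < config.postprandial_missing_many_frac:
                miss = rng.choice(len(t), size=2, replace=False)
                values[miss] = np.nan
            elif u < config.postprandial_missing_many_frac + config.postprandial_missing_one_frac:
                values[int(rng.integers(len(t)))] = np.nan
            for ti, vi in zip(t, values):
                rows.append({"sample_id": sid, "marker": marker, "time_min": float(ti), "value": vi})
    return pd.DataFrame(rows)


def inject_missingness(
    blocks: dict[str, FeatureBlock], config: SynthConfig
) -> tuple[dict[str, FeatureBlock], list]:
    """Drop whole samples per block and report the complete-case subset.

    Fractions come from ``config.missingness`` (block label -> fraction of
    samples dropped).  Returns ``(blocks, complete_case_sample_ids)``; the
    complete-case set is the intersection of all block sample sets.
    """
    rng = np.random.default_rng(config.seed + 3)
    out: dict[str, FeatureBlock] = {}
    for label, block in blocks.items():
        frac = config.missingness.get(label, 0.0)
        if frac >= 1:
            raise ValueError(f"drop fraction for block {label!r} must be < 1")
        if frac > 0:
            n_drop = int(np.floor(frac * len(block.data)))
            drop = rng.choice(block.data.index, size=n_drop, replace=False)
            out[label] = FeatureBlock(label, block.data.drop(index=drop))
        else:
            out[label] = block
    complete = None
    for block in out.values():
        ids = set(block.data.index)
        complete = ids if complete is None else complete & ids
    complete_sorted = sorted(complete or [])
    logger.info("complete-case subset: %d samples", len(complete_sorted))
    return out, complete_sorted


def simulate_all(config: SynthConfig):
    """Convenience wrapper: cohort, truth, blocks (with missingness) and
    postprandial series in one call."""
    cohort, truth = simulate_cohort(config)
    blocks = simulate_omics_blocks(config, cohort, truth)
    blocks, complete = inject_missingness(blocks, config)
    postprandial = simulate_postprandial(config, cohort, truth)
    return cohort, truth, blocks, postprandial, complete


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_blocks(blocks: dict[str, FeatureBlock], outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, block in blocks.items():
        safe = label.replace("/", "_")
        block.data.to_csv(outdir / f"block_{safe}.tsv", sep="\t", index_label="sample_id")


def read_block(path, label: str | None = None) -> FeatureBlock:
    from pathlib import Path

    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col="sample_id")
    if label is None:
        label = path.stem.removeprefix("block_")
    return FeatureBlock(label, data)
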