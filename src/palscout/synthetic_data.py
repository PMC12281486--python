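"""Synthetic experiments with known ground truth.

Two generators mirror the designs the pipeline targets:

* a competition photoaffinity-labeling (PAL) enrichment experiment with three
  arms — vehicle, probe, and probe + excess parent compound — and paired
  replicates (matched culture batches);
* an untargeted metabolomics group experiment with several biological groups
  plus repeated pooled-QC injections.

Intensities are log-normal: per-feature baselines are drawn on the log2 scale
and all effects act additively in log2 (multiplicatively in raw intensity),
which matches DIA/LC-MS intensity behavior and makes median normalization
non-trivial.  A shared per-(feature, replicate) offset induces the pairing
correlation the paired t-test exploits.  Missingness is uniform (MCAR).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import (
    ROLE_BIOLOGICAL,
    ROLE_POOLED_QC,
    AbundanceMatrix,
    MetaboliteTable,
    SampleDesign,
    ValidationError,
)

COND_VEHICLE = "vehicle"
COND_PROBE = "probe"
COND_COMPETITION = "competition"

TRUTH_SPECIFIC = "specific"
TRUTH_NONSPECIFIC = "nonspecific"
TRUTH_BACKGROUND = "background"


@dataclass
class PalSimConfig:
    """Competition PAL experiment generator settings.

    ``enrichment_log2`` is the probe-over-vehicle effect of spiked binders;
    ``competition_log2`` is the probe-over-competition effect of *specific*
    binders (their enrichment is lost when the parent compound competes;
    nonspecific binders keep full enrichment under competition).  Baselines
    are N(baseline_log2_mean, baseline_log2_sd^2) per feature; noise is
    N(0, noise_sd^2) per cell; ``pair_effect_sd`` scales the shared
    per-(feature, replicate) batch offset.
    """

    n_features: int = 3000
    n_replicates: int = 8
    n_specific: int = 10
    n_nonspecific: int = 10
    enrichment_log2: float = 2.5
    competition_log2: float = 2.5
    noise_sd: float = 0.4
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    pair_effect_sd: float = 0.1
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_specific + self.n_nonspecific > self.n_features:
            raise ValidationError("more spiked features than features")
        if not self.noise_sd > 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates")


def simulate_pal_experiment(
    cfg: PalSimConfig,
) -> tuple[AbundanceMatrix, SampleDesign, pd.DataFrame]:
    """Generate (raw AbundanceMatrix, SampleDesign, truth table).

    The truth table has one row per feature: ``class`` in
    {specific, nonspecific, background}, ``true_enrichment`` (probe over
    vehicle, log2) and ``true_competition_loss`` (probe over competition,
    log2).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    F, R = cfg.n_features, cfg.n_replicates
    width = len(str(F))
    features = [f"F{i + 1:0{width}d}" for i in range(F)]

    classes = np.array(
        [TRUTH_SPECIFIC] * cfg.n_specific
        + [TRUTH_NONSPECIFIC] * cfg.n_nonspecific
        + [TRUTH_BACKGROUND] * (F - cfg.n_specific - cfg.n_nonspecific)
    )
    spiked = classes != TRUTH_BACKGROUND
    enrich = np.where(spiked, cfg.enrichment_log2, 0.0)
    comp_loss = np.where(classes == TRUTH_SPECIFIC, cfg.competition_log2, 0.0)

    # condition effect per feature (log2): columns vehicle, probe, competition
    eff = np.stack(
        [np.zeros(F), enrich, enrich - comp_loss], axis=1
    )

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=F)
    pair_off = rng.normal(0.0, cfg.pair_effect_sd, size=(F, R))

    conditions = [COND_VEHICLE, COND_PROBE, COND_COMPETITION]
    cols, col_cond, col_rep = [], [], []
    for cond_idx, cond in enumerate(conditions):
        for r in range(R):
            cols.append(f"{cond}_{r + 1}")
            col_cond.append(cond_idx)
            col_rep.append(r)
    log2 = (
        baseline[:, None]
        + eff[:, col_cond]
        + pair_off[:, col_rep]
        + rng.normal(0.0, cfg.noise_sd, size=(F, len(cols)))
    )
    raw = np.exp2(log2)
    if cfg.missing_rate > 0:
        raw[rng.random(size=raw.shape) < cfg.missing_rate] = np.nan

    matrix = AbundanceMatrix(
        pd.DataFrame(raw, index=features, columns=cols), scale="raw"
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": cols,
                "condition": [conditions[c] for c in col_cond],
                "replicate_index": [r + 1 for r in col_rep],
                "role": ROLE_BIOLOGICAL,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "feature_id": features,
            "class": classes,
            "true_enrichment": enrich,
            "true_competition_loss": comp_loss,
        }
    )
    return matrix, design, truth


@dataclass
class MetaboSimConfig:
    """Untargeted metabolomics group experiment generator settings.

    Three biological groups of five replicates (GFP control, GFP + drug,
    enzyme overexpression) plus pooled-QC injections by default.  Affected
    features are shifted by ``effect_log2`` in ``affected_group``.  Each
    feature's pooled-QC replicates get a technical CV drawn uniformly from
    ``qc_cv_range``, so a controllable fraction of features violates the 25%
    QC rule.  Annotation confidence levels are assigned multinomially with
    ``annotation_level_props`` over (L1, L2, L3, unannotated).
    """

    n_features: int = 2000
    groups: tuple[tuple[str, int], ...] = (
        ("GFP_DMSO", 5),
        ("GFP_VX445", 5),
        ("SCCPDH_DMSO", 5),
    )
    affected_group: str = "SCCPDH_DMSO"
    n_affected: int = 20
    effect_log2: float = 3.0
    noise_sd: float = 0.4
    baseline_log2_mean: float = 18.0
    baseline_log2_sd: float = 2.0
    qc_replicates: int = 5
    qc_cv_range: tuple[float, float] = (0.02, 0.30)
    annotation_level_props: tuple[float, float, float, float] = (
        0.10,
        0.20,
        0.30,
        0.40,
    )
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.annotation_level_props) - 1.0) > 1e-9:
            raise ValidationError("annotation_level_props must sum to 1")
        if self.affected_group not in {g for g, _ in self.groups}:
            raise ValidationError(
                f"affected_group {self.affected_group!r} not among groups"
            )
        if self.n_affected > self.n_features:
            raise ValidationError("n_affected exceeds n_features")
        lo, hi = self.qc_cv_range
        if not (0 <= lo <= hi):
            raise ValidationError("invalid qc_cv_range")


def simulate_metabolomics(
    cfg: MetaboSimConfig,
) -> tuple[MetaboliteTable, SampleDesign, set[str]]:
    """Generate (raw MetaboliteTable, SampleDesign, affected-feature set)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    F = cfg.n_features
    width = len(str(F))
    features = [f"M{i + 1:0{width}d}" for i in range(F)]
    affected = np.zeros(F, dtype=bool)
    affected[: cfg.n_affected] = True

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=F)

    cols, conds, reps, roles = [], [], [], []
    blocks = []
    for group, n in cfg.groups:
        shift = cfg.effect_log2 if group == cfg.affected_group else 0.0
        eff = np.where(affected, shift, 0.0)
        block = (
            baseline[:, None]
            + eff[:, None]
            + rng.normal(0.0, cfg.noise_sd, size=(F, n))
        )
        blocks.append(np.exp2(block))
        for r in range(n):
            cols.append(f"{group}_{r + 1}")
            conds.append(group)
            reps.append(r + 1)
            roles.append(ROLE_BIOLOGICAL)

    bio = np.concatenate(blocks, axis=1)

    # pooled QC: replicate injections of the pooled biological mean with a
    # per-feature technical CV; a log-normal with sigma_ln = sqrt(ln(1+cv^2))
    # has exactly that coefficient of variation
    pooled_mean = np.nanmean(bio, axis=1)
    cv_target = rng.uniform(*cfg.qc_cv_range, size=F)
    sigma_ln = np.sqrt(np.log1p(cv_target**2))
    qc = pooled_mean[:, None] * np.exp(
        rng.normal(0.0, 1.0, size=(F, cfg.qc_replicates)) * sigma_ln[:, None]
        - 0.5 * sigma_ln[:, None] ** 2
    )
    for r in range(cfg.qc_replicates):
        cols.append(f"QC_{r + 1}")
        conds.append("pooled_qc")
        reps.append(r + 1)
        roles.append(ROLE_POOLED_QC)

    raw = np.concatenate([bio, qc], axis=1)
    matrix = AbundanceMatrix(
        pd.DataFrame(raw, index=features, columns=cols), scale="raw"
    )
    levels = rng.choice(
        ["L1", "L2", "L3", "unannotated"],
        size=F,
        p=cfg.annotation_level_props,
    )
    annotations = pd.DataFrame(
        {
            "metabolite_name": [f"metabolite_{f}" for f in features],
            "annotation_level": levels,
        },
        index=features,
    )
    table = MetaboliteTable(matrix, annotations)
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": cols,
                "condition": conds,
                "replicate_index": reps,
                "role": roles,
            }
        )
    )
    truth = set(np.array(features)[affected])
    return table, design, truth
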