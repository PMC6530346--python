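"""Synthetic two-channel 2D-DiGE experiments with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for the five-group, 59-gel rat peritoneal-dialysis experiment:

* log-normal spot volumes with a gel-level log2 intercept ``b_g``
  shared by the two channels of a gel (the between-gel variation the
  internal pooled standard exists to remove);
* a per-sample **plasma contamination fraction** that multiplies
  plasma-class spot volumes only, drawn from a logit-normal
  distribution whose mean may differ between treatment groups.  The
  internal standard is a single pool, so its contamination is fixed.
  Group-shifted contamination is the confound that breaks total-sum
  normalization while leaving cellular-spot generating parameters
  untouched;
* treatment effects on a subset of **cellular** spots: a fluid effect
  per dialysis-fluid arm, and a smaller additive (alanyl-glutamine)
  effect on a sub-subset of the fluid-affected spots;
* detection-limit censoring: volumes below ``detection_limit`` are
  recorded as exact zeros, as produced by the scanner/image software.

``simulate_experiment`` returns the spot matrix, design, annotation and
a :class:`SimulationTruth` with every latent quantity, so parameter
recovery and error control can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io import (
    AnnotationTable,
    DesignTable,
    Group,
    SpotAnnotation,
    SpotClass,
    SpotMatrix,
    ValidationError,
)
from .models import COEFFICIENTS, design_matrix

#: gels per group in the study design (59 gels total)
DEFAULT_GROUP_SIZES = {
    Group.control: 6,
    Group.SCB: 14,
    Group.SCB_AG: 13,
    Group.DCB: 15,
    Group.DCB_AG: 11,
}


@dataclass
class EffectLaw:
    """Distribution of per-spot true log2 effects.

    ``kind``:
      * ``fixed`` — every affected spot gets exactly ``value``;
      * ``signed_uniform`` — magnitude uniform on [low, high], random sign;
      * ``normal`` — N(0, sd).
    """

    kind: str = "signed_uniform"
    value: float = 0.8
    low: float = 0.5
    high: float = 1.5
    sd: float = 0.8

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, float(self.value))
        if self.kind == "signed_uniform":
            mag = rng.uniform(self.low, self.high, n)
            sign = rng.choice([-1.0, 1.0], n)
            return mag * sign
        if self.kind == "normal":
            return rng.normal(0.0, self.sd, n)
        raise ValidationError(f"unknown effect law kind {self.kind!r}")


@dataclass
class EffectSpec:
    """How many spots a coefficient affects and with what effect sizes."""

    n_affected: int
    law: EffectLaw = field(default_factory=EffectLaw)


@dataclass
class ContaminationSpec:
    """Per-sample plasma contamination fraction, logit-normal by group.

    ``mean`` maps group name -> mean contamination fraction; per gel a
    fraction is drawn as ``sigmoid(logit(mean) + N(0, logit_sd))``.
    The internal pooled standard carries the fixed ``ips_fraction``.
    """

    mean: dict[str, float] = field(
        default_factory=lambda: {
            "control": 0.15,
            "SCB": 0.35,
            "SCB_AG": 0.35,
            "DCB": 0.35,
            "DCB_AG": 0.35,
        }
    )
    logit_sd: float = 0.35
    ips_fraction: float = 0.30

    @classmethod
    def uniform(cls, mean: float = 0.25, logit_sd: float = 0.35) -> "ContaminationSpec":
        """Same contamination distribution in every group (no confound)."""
        return cls(mean={g.name: mean for g in Group}, logit_sd=logit_sd, ips_fraction=mean)

    def draw(self, rng: np.random.Generator, group: Group) -> float:
        m = float(self.mean[group.name])
        logit = np.log(m / (1.0 - m)) + rng.normal(0.0, self.logit_sd)
        return float(1.0 / (1.0 + np.exp(-logit)))


@dataclass
class SimulationConfig:
    """Generative parameters; defaults emulate the study conditions."""

    n_spots: int = 744
    frac_plasma: float = 0.30
    frac_unidentified: float = 0.32
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g.name: n for g, n in DEFAULT_GROUP_SIZES.items()}
    )
    sigma_gel: float = 0.5
    sigma_eps: float = 0.25
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    fluid_effect: EffectSpec = field(default_factory=lambda: EffectSpec(200))
    additive_effect: EffectSpec = field(
        default_factory=lambda: EffectSpec(60, EffectLaw("signed_uniform", low=0.2, high=0.5))
    )
    detection_limit: float = 16.0
    #: mean/sd of baseline log2 volume per spot class
    base_log2: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "cellular": (10.0, 1.8),
            "plasma": (11.0, 1.2),
            "unidentified": (7.0, 1.5),
        }
    )
    #: constant sample-vs-IPS log2 offset (30 ug sample vs 27 ug standard)
    channel_offset: float = float(np.log2(30 / 27))
    #: unique identified proteins per identified spot (one protein, many spots)
    proteins_per_spot: float = 222 / 505
    seed: int = 0

    def validate(self) -> None:
        if self.n_spots < 1:
            raise ValidationError("n_spots must be >= 1")
        for name in ("frac_plasma", "frac_unidentified"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_plasma + self.frac_unidentified > 1.0:
            raise ValidationError("frac_plasma + frac_unidentified must be <= 1")
        for g in Group:
            if self.group_sizes.get(g.name, 0) < 1:
                raise ValidationError(f"group_sizes[{g.name}] must be >= 1")
        if self.sigma_gel < 0 or self.sigma_eps < 0:
            raise ValidationError("sigma_gel and sigma_eps must be >= 0")
        if self.detection_limit < 0:
            raise ValidationError("detection_limit must be >= 0")
        n_cellular = self.n_spots - round(self.n_spots * self.frac_plasma) - round(
            self.n_spots * self.frac_unidentified
        )
        if self.fluid_effect.n_affected > n_cellular:
            raise ValidationError(
                f"fluid_effect.n_affected ({self.fluid_effect.n_affected}) exceeds the "
                f"number of cellular spots ({n_cellular})"
            )
        if self.additive_effect.n_affected > self.fluid_effect.n_affected:
            raise ValidationError(
                "additive-affected spots must be a subset of fluid-affected spots"
            )
        for g in Group:
            m = self.contamination.mean.get(g.name)
            if m is None or not 0.0 < m < 1.0:
                raise ValidationError(f"contamination mean for {g.name} must be in (0, 1)")
        if not 0.0 < self.contamination.ips_fraction < 1.0:
            raise ValidationError("contamination.ips_fraction must be in (0, 1)")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "SimulationConfig":
        """Global null: no treatment effects, no group-shifted contamination."""
        kwargs.setdefault("fluid_effect", EffectSpec(0))
        kwargs.setdefault("additive_effect", EffectSpec(0))
        kwargs.setdefault("contamination", ContaminationSpec.uniform())
        return cls(seed=seed, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return config_from_dict(yaml.safe_load(fh) or {})


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "contamination" in d and isinstance(d["contamination"], dict):
        d["contamination"] = ContaminationSpec(**d["contamination"])
    for key in ("fluid_effect", "additive_effect"):
        if key in d and isinstance(d[key], dict):
            spec = dict(d[key])
            if isinstance(spec.get("law"), dict):
                spec["law"] = EffectLaw(**spec["law"])
            d[key] = EffectSpec(**spec)
    if "base_log2" in d:
        d["base_log2"] = {k: tuple(v) for k, v in d["base_log2"].items()}
    return SimulationConfig(**d)


@dataclass
class SimulationTruth:
    """Latent quantities behind one simulated experiment."""

    spot_ids: list[str]
    gel_ids: list[str]
    classes: list[SpotClass]
    effects: dict[str, np.ndarray]  # coefficient -> per-spot true log2 effect
    contamination: np.ndarray  # per-gel drawn plasma fraction
    gel_intercepts: np.ndarray  # per-gel b_g (log2)
    baseline_log2: np.ndarray  # per-spot baseline abundance


def truth_effect_table(truth: SimulationTruth) -> pd.DataFrame:
    """Per-spot table of true log2 coefficients (lossless projection)."""
    data = {"spot_id": truth.spot_ids}
    for coef in COEFFICIENTS:
        data[coef] = truth.effects[coef]
    return pd.DataFrame(data)


def _assign_proteins(
    rng: np.random.Generator, idx: np.ndarray, prefix: str, per_spot: float
) -> dict[int, tuple[str, str]]:
    """Map identified spot indices to (accession, gene), several spots per protein."""
    n_spots = idx.size
    if n_spots == 0:
        return {}
    n_prot = max(1, int(round(n_spots * per_spot)))
    order = rng.permutation(idx)
    assignment: dict[int, tuple[str, str]] = {}
    for rank, spot in enumerate(order):
        p = rank if rank < n_prot else int(rng.integers(0, n_prot))
        assignment[int(spot)] = (f"{prefix}{p + 1:04d}", f"G{prefix}{p + 1:04d}")
    return assignment


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[SpotMatrix, DesignTable, AnnotationTable, SimulationTruth]:
    """Draw one experiment; identical configs give bit-identical outputs."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_spots
    n_plasma = int(round(n * config.frac_plasma))
    n_unid = int(round(n * config.frac_unidentified))
    n_cellular = n - n_plasma - n_unid

    spot_ids = [f"s{i + 1:04d}" for i in range(n)]
    class_codes = np.concatenate(
        [
            np.full(n_plasma, 0),
            np.full(n_cellular, 1),
            np.full(n_unid, 2),
        ]
    )
    rng.shuffle(class_codes)
    classes = [
        (SpotClass.plasma, SpotClass.cellular, SpotClass.unidentified)[c]
        for c in class_codes
    ]
    plasma_idx = np.flatnonzero(class_codes == 0)
    cellular_idx = np.flatnonzero(class_codes == 1)

    # design
    gel_ids, groups = [], {}
    for g in Group:  # fixed enum order -> deterministic gel naming
        for _ in range(config.group_sizes[g.name]):
            gid = f"gel{len(gel_ids) + 1:02d}"
            gel_ids.append(gid)
            groups[gid] = g
    design = DesignTable(groups)
    n_gels = len(gel_ids)
    x = design_matrix(design, gel_ids)  # (n_gels, 4)

    # annotation: identified spots (plasma + cellular) map onto fewer proteins
    proteins = {}
    proteins.update(_assign_proteins(rng, plasma_idx, "P", config.proteins_per_spot))
    proteins.update(_assign_proteins(rng, cellular_idx, "C", config.proteins_per_spot))
    annotation = AnnotationTable(
        [
            SpotAnnotation(
                spot_id=spot_ids[i],
                accession=proteins.get(i, (None, None))[0],
                gene=proteins.get(i, (None, None))[1],
                spot_class=classes[i],
            )
            for i in range(n)
        ]
    )

    # true effects on cellular spots; additive-affected is a sub-subset
    effects = {coef: np.zeros(n) for coef in COEFFICIENTS}
    for fluid, additive in (("fluid_SCB", "additive_SCB_AG"), ("fluid_DCB", "additive_DCB_AG")):
        n_f = config.fluid_effect.n_affected
        if n_f > 0:
            chosen = rng.choice(cellular_idx, size=n_f, replace=False)
            effects[fluid][chosen] = config.fluid_effect.law.draw(rng, n_f)
            n_a = config.additive_effect.n_affected
            if n_a > 0:
                sub = rng.choice(chosen, size=n_a, replace=False)
                effects[additive][sub] = config.additive_effect.law.draw(rng, n_a)

    # latent per-gel quantities
    b_g = rng.normal(0.0, config.sigma_gel, n_gels)
    contamination = np.array(
        [config.contamination.draw(rng, groups[g]) for g in gel_ids]
    )
    c0 = config.contamination.ips_fraction
    # plasma volumes scale with contamination odds relative to the pool
    plasma_log2_shift = np.log2(
        (contamination / (1.0 - contamination)) / (c0 / (1.0 - c0))
    )

    base = np.empty(n)
    for cls_name, (mu, sd) in config.base_log2.items():
        mask = np.array([c.value == cls_name for c in classes])
        base[mask] = rng.normal(mu, sd, int(mask.sum()))
    if config.detection_limit > 0:
        # spot detection runs on a fused image: an exported spot is seen on
        # some gel, so baselines sit above the limit (zeros still arise from
        # per-channel noise dipping below it)
        base = np.maximum(base, np.log2(config.detection_limit) + 0.5)

    treat = np.zeros((n, n_gels))
    for k, coef in enumerate(COEFFICIENTS):
        treat += np.outer(effects[coef], x[:, k])

    is_plasma = (class_codes == 0).astype(float)
    sample_log2 = (
        base[:, None]
        + b_g[None, :]
        + config.channel_offset
        + treat
        + np.outer(is_plasma, plasma_log2_shift)
        + rng.normal(0.0, config.sigma_eps, (n, n_gels))
    )
    ips_log2 = base[:, None] + b_g[None, :] + rng.normal(0.0, config.sigma_eps, (n, n_gels))

    sample = np.exp2(sample_log2)
    ips = np.exp2(ips_log2)
    sample[sample < config.detection_limit] = 0.0
    ips[ips < config.detection_limit] = 0.0

    matrix = SpotMatrix(spot_ids, gel_ids, sample, ips)
    truth = SimulationTruth(
        spot_ids=spot_ids,
        gel_ids=gel_ids,
        classes=classes,
        effects=effects,
        contamination=contamination,
        gel_intercepts=b_g,
        baseline_log2=base,
    )
    return matrix, design, annotation, truth
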