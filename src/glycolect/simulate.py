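"""Synthetic slide simulator with planted, analytically known ground truth.

The simulator reproduces the replicate structure of the assay — by default
3 replicate spots per lectin per block, 3 blocks per slide, 3 slides per
group (9 blocks/group) — around one pooled biological sample per group, so
all replication is technical.

Noise model (documented artifact choices, not calibrated to any dataset):
multiplicative mean-one log-normal noise per spot, shared log-normal
multipliers per block and per slide, additive truncated-normal background,
saturation clipping, and Bernoulli spot dropout (flag -100).

Planted fold changes act on the *raw* net intensity of a lectin.  Because
downstream NFIs are closed (they sum to 1 within a block), the measurable
NFI ratio for lectin ``l`` with fold ``f_l`` is

    (f_l * mu_l / sum_k f_k * mu_k) / (mu_l / sum_k mu_k)

which :func:`expected_nfi_ratio` returns in closed form; a single fold ``f``
on a lectin of baseline NFI weight ``w`` gives ``f / (1 + (f - 1) * w)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from glycolect.array_core import GroupManifest, Panel, SpotRecord, default_panel
from glycolect.errors import ConfigError

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "expected_nfi_ratio",
]

DROPOUT_FLAG = -100


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: id, model/control role, slide count, and an
    optional per-group fold map overriding the config-level one."""

    group_id: str
    role: str = "model"
    n_slides: int = 3
    fold: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("model", "control"):
            raise ConfigError(f"group {self.group_id!r}: bad role {self.role!r}")
        if self.n_slides < 1:
            raise ConfigError(f"group {self.group_id!r}: n_slides must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    panel: Panel
    groups: tuple[GroupSpec, ...]
    #: per-lectin mean log net intensity; a scalar applies to every lectin
    baseline_mu: Union[float, Mapping[str, float]] = 8.0
    #: fold map applied to every model-role group without its own ``fold``
    planted_fold: Mapping[str, float] = field(default_factory=dict)
    spot_cv: float = 0.1
    block_sd: float = 0.05
    slide_sd: float = 0.05
    bg_level: float = 100.0
    bg_sd: float = 10.0
    saturation: float = 65535.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        gids = [g.group_id for g in self.groups]
        if len(set(gids)) != len(gids):
            raise ConfigError("duplicate group ids")
        for val, name in (
            (self.spot_cv, "spot_cv"),
            (self.block_sd, "block_sd"),
            (self.slide_sd, "slide_sd"),
            (self.bg_sd, "bg_sd"),
            (self.bg_level, "bg_level"),
        ):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.saturation <= self.bg_level:
            raise ConfigError("saturation must exceed bg_level")
        for g in self.groups:
            for lec, f in {**dict(self.planted_fold), **dict(g.fold)}.items():
                if lec not in self.panel:
                    raise ConfigError(f"planted fold names unknown lectin {lec!r}")
                if f <= 0:
                    raise ConfigError(f"planted fold for {lec!r} must be > 0")

    # -- derived quantities -------------------------------------------------

    def baseline_net(self, lectin: str) -> float:
        """Noise-free net intensity exp(mu) for one lectin."""
        if lectin not in self.panel:
            raise KeyError(lectin)
        if isinstance(self.baseline_mu, Mapping):
            return math.exp(self.baseline_mu[lectin])
        return math.exp(self.baseline_mu)

    def fold_map(self, group: GroupSpec) -> dict[str, float]:
        folds = {name: 1.0 for name in self.panel.names}
        if group.role == "model" and not group.fold:
            folds.update(self.planted_fold)
        folds.update(group.fold)
        return folds

    def true_net(self, group: GroupSpec, lectin: str) -> float:
        return self.baseline_net(lectin) * self.fold_map(group)[lectin]

    def model_groups(self) -> tuple[GroupSpec, ...]:
        return tuple(g for g in self.groups if g.role == "model")

    def control_groups(self) -> tuple[GroupSpec, ...]:
        return tuple(g for g in self.groups if g.role == "control")

    def group(self, group_id: str) -> GroupSpec:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    # -- (de)serialization for the CLI -------------------------------------

    @classmethod
    def from_dict(cls, payload: Mapping, panel: Optional[Panel] = None) -> "SimulationConfig":
        payload = dict(payload)
        if panel is None:
            panel = default_panel()
        groups = tuple(
            GroupSpec(
                g["group_id"],
                g.get("role", "model"),
                int(g.get("n_slides", 3)),
                dict(g.get("fold", {})),
            )
            for g in payload.pop("groups")
        )
        payload.pop("panel", None)
        return cls(panel=panel, groups=groups, **payload)

    def to_dict(self) -> dict:
        return {
            "groups": [
                {"group_id": g.group_id, "role": g.role, "n_slides": g.n_slides,
                 "fold": dict(g.fold)}
                for g in self.groups
            ],
            "baseline_mu": (dict(self.baseline_mu)
                            if isinstance(self.baseline_mu, Mapping) else self.baseline_mu),
            "planted_fold": dict(self.planted_fold),
            "spot_cv": self.spot_cv,
            "block_sd": self.block_sd,
            "slide_sd": self.slide_sd,
            "bg_level": self.bg_level,
            "bg_sd": self.bg_sd,
            "saturation": self.saturation,
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free quantities implied by a config: raw net intensities, their
    closed (NFI) versions, and every model-vs-control expected NFI ratio."""

    true_net: Mapping[str, Mapping[str, float]]
    expected_nfi: Mapping[str, Mapping[str, float]]
    expected_ratio: Mapping[tuple[str, str], Mapping[str, float]]


@dataclass(frozen=True)
class SimulatedExperiment:
    slides: Mapping[str, tuple[SpotRecord, ...]]
    truth: GroundTruth
    manifests: tuple[GroupManifest, ...]


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    names = config.panel.names
    true_net = {
        g.group_id: {lec: config.true_net(g, lec) for lec in names}
        for g in config.groups
    }
    expected_nfi = {}
    for gid, nets in true_net.items():
        total = sum(nets.values())
        expected_nfi[gid] = {lec: nets[lec] / total for lec in names}
    expected_ratio = {}
    for model in config.model_groups():
        for control in config.control_groups():
            expected_ratio[(model.group_id, control.group_id)] = {
                lec: expected_nfi[model.group_id][lec] / expected_nfi[control.group_id][lec]
                for lec in names
            }
    return GroundTruth(true_net, expected_nfi, expected_ratio)


def expected_nfi_ratio(
    config: SimulationConfig,
    lectin: str,
    model: Optional[str] = None,
    control: Optional[str] = None,
) -> float:
    """Closed-form expected NFI ratio (model/control) for one lectin.

    Defaults to the first model-role and first control-role groups.  Equals
    the planted fold exactly when the lectin's baseline weight tends to 0.
    """
    if lectin not in config.panel:
        raise KeyError(lectin)
    models, controls = config.model_groups(), config.control_groups()
    if model is None:
        if not models:
            raise ConfigError("config has no model-role group")
        model = models[0].group_id
    if control is None:
        if not controls:
            raise ConfigError("config has no control-role group")
        control = controls[0].group_id
    truth = _ground_truth(config)
    return truth.expected_ratio[(model, control)][lectin]


def simulate_experiment(config: SimulationConfig,
                        seed: Optional[int] = None) -> SimulatedExperiment:
    """Simulate all slides of an experiment.

    Identical seeds give byte-identical output; the ground truth depends
    only on the config, never on the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = config.panel
    names = panel.names
    n_spots = panel.spots_per_lectin_per_block
    spot_sigma = math.sqrt(math.log1p(config.spot_cv ** 2))

    truth = _ground_truth(config)
    slides: dict[str, tuple[SpotRecord, ...]] = {}
    manifests = []

    for group in config.groups:
        nets = np.array([truth.true_net[group.group_id][lec] for lec in names])
        slide_ids = []
        for s in range(1, group.n_slides + 1):
            slide_id = f"{group.group_id}-s{s}"
            slide_ids.append(slide_id)
            slide_mult = rng.lognormal(0.0, config.slide_sd) if config.slide_sd > 0 else 1.0
            records: list[SpotRecord] = []
            for block in range(1, panel.blocks_per_slide + 1):
                block_mult = rng.lognormal(0.0, config.block_sd) if config.block_sd > 0 else 1.0
                # mean-one multiplicative spot noise
                if spot_sigma > 0:
                    noise = rng.lognormal(-spot_sigma ** 2 / 2, spot_sigma,
                                          size=(len(names), n_spots))
                else:
                    noise = np.ones((len(names), n_spots))
                bg = np.maximum(
                    0.0, rng.normal(config.bg_level, config.bg_sd, size=(len(names), n_spots))
                ) if config.bg_sd > 0 else np.full((len(names), n_spots), config.bg_level)
                dropped = (rng.random(size=(len(names), n_spots)) < config.dropout_rate
                           ) if config.dropout_rate > 0 else np.zeros((len(names), n_spots), bool)
                fg = np.minimum(
                    config.saturation,
                    nets[:, None] * slide_mult * block_mult * noise + bg,
                )
                for li, lectin in enumerate(names):
                    for spot in range(n_spots):
                        records.append(
                            SpotRecord(
                                slide_id=slide_id,
                                block=block,
                                row=li + 1,
                                column=spot + 1,
                                lectin=lectin,
                                fg_median=float(fg[li, spot]),
                                bg_median=float(bg[li, spot]),
                                flag=DROPOUT_FLAG if dropped[li, spot] else 0,
                            )
                        )
            slides[slide_id] = tuple(records)
        manifests.append(GroupManifest(group.group_id, tuple(slide_ids), group.role))

    return SimulatedExperiment(slides, truth, tuple(manifests))
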