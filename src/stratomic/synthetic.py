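"""Seeded synthetic cohort generator.

Emits cohorts with the statistical structure the downstream analysis
assumes: log-normal protein intensities with correlated clusters and
group-specific effects, intensity-dependent (MNAR) plus uniform (MCAR)
missingness, and clinical features with group-shifted means.  Everything is
driven by a single root generator so two calls with the same config are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import GROUPS, ClinicalTable, CohortBundle, ConfigError, ProteinMatrix

__all__ = [
    "PanelFeature",
    "ClusterSpec",
    "SyntheticConfig",
    "generate_cohort",
    "generate_external_cohort",
    "preset",
    "PRESETS",
]

DEFAULT_SEED = 20180101


@dataclass(frozen=True)
class PanelFeature:
    """An injected discriminant feature: shifted in ``target_group`` only."""

    name: str
    target_group: str
    effect_size: float  # in SD units of the feature
    direction: str  # "up" | "down"

    def signed_effect(self) -> float:
        return self.effect_size if self.direction == "up" else -self.effect_size


@dataclass(frozen=True)
class ClusterSpec:
    """A set of protein features sharing a common latent factor."""

    members: tuple[str, ...]
    correlation: float


@dataclass(frozen=True)
class SyntheticConfig:
    group_sizes: Mapping[str, int] = field(default_factory=lambda: {"CTRL": 66, "DLP": 55, "AT": 60})
    n_proteins: int = 300
    n_clinical: int = 20
    n_binary_clinical: int = 0
    panel_spec: tuple[PanelFeature, ...] = ()
    base_log2_mean: float = 22.0
    base_log2_sd: float = 1.0
    protein_mean_spread: float = 2.5  # between-protein SD of mean log2 intensity
    cluster_spec: tuple[ClusterSpec, ...] = ()
    mnar_steepness: float = 0.0  # 0 disables intensity-dependent censoring
    mnar_midpoint: float = 18.0  # log2 intensity of 50% censoring probability
    mcar_rate: float = 0.0
    clinical_missing_rate: float = 0.0
    clinical_shift_sd: float = 0.0  # SD of random per-(group,feature) clinical shifts
    seed: int = DEFAULT_SEED

    # -- naming ----------------------------------------------------------

    def protein_names(self) -> list[str]:
        return [f"PROT{i:04d}" for i in range(1, self.n_proteins + 1)]

    def clinical_names(self) -> list[str]:
        num = [f"CLIN{i:02d}" for i in range(1, self.n_clinical + 1)]
        binary = [f"BIN{i:02d}" for i in range(1, self.n_binary_clinical + 1)]
        return num + binary

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigError("group_sizes is empty")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n <= 0:
                raise ConfigError(f"group size for {g!r} must be positive")
        if self.n_proteins <= 0 or self.n_clinical < 0 or self.n_binary_clinical < 0:
            raise ConfigError("feature counts must be positive")
        for rate, name in (
            (self.mcar_rate, "mcar_rate"),
            (self.clinical_missing_rate, "clinical_missing_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        known = set(self.protein_names()) | set(self.clinical_names())
        for pf in self.panel_spec:
            if pf.name not in known:
                raise ConfigError(
                    f"panel feature {pf.name!r} is not among the generated features "
                    f"(n_proteins={self.n_proteins}, n_clinical={self.n_clinical})"
                )
            if pf.target_group not in self.group_sizes:
                raise ConfigError(f"panel feature {pf.name!r} targets unknown group {pf.target_group!r}")
            if pf.direction not in ("up", "down"):
                raise ConfigError(f"panel feature {pf.name!r}: direction must be 'up' or 'down'")
        proteins = set(self.protein_names())
        for cs in self.cluster_spec:
            if not 0.0 <= cs.correlation < 1.0:
                raise ConfigError("within-cluster correlation must lie in [0, 1)")
            missing = set(cs.members) - proteins
            if missing:
                raise ConfigError(f"cluster members {sorted(missing)} are not generated proteins")


def _group_vector(config: SyntheticConfig) -> tuple[list[str], pd.Series]:
    sample_ids: list[str] = []
    groups: list[str] = []
    for g in GROUPS:
        if g not in config.group_sizes:
            continue
        for i in range(1, config.group_sizes[g] + 1):
            sample_ids.append(f"{g}{i:03d}")
            groups.append(g)
    return sample_ids, pd.Series(groups, index=sample_ids, name="group")


def _protein_log2(config: SyntheticConfig, groups: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    names = config.protein_names()
    n, p = len(groups), len(names)
    mu = config.base_log2_mean + rng.normal(0.0, config.protein_mean_spread, size=p)
    # injected panel proteins sit at the base intensity: well-quantified
    # markers rather than near-detection-limit ones
    panel_proteins = {pf.name for pf in config.panel_spec}
    for j, name in enumerate(names):
        if name in panel_proteins:
            mu[j] = config.base_log2_mean
    z = rng.standard_normal((n, p))
    # correlated clusters: members mix a shared latent factor so that any two
    # members correlate at exactly the requested rho
    col = {name: j for j, name in enumerate(names)}
    for cs in config.cluster_spec:
        shared = rng.standard_normal(n)
        a, b = math.sqrt(cs.correlation), math.sqrt(1.0 - cs.correlation)
        for m in cs.members:
            z[:, col[m]] = a * shared + b * rng.standard_normal(n)
    values = mu[None, :] + config.base_log2_sd * z
    for pf in config.panel_spec:
        if pf.name in col:
            mask = (groups == pf.target_group).to_numpy()
            values[mask, col[pf.name]] += pf.signed_effect() * config.base_log2_sd
    return pd.DataFrame(values, index=groups.index, columns=names)


def _apply_missingness(
    log2: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw-scale matrix with MNAR censoring then MCAR dropout applied."""
    vals = log2.to_numpy()
    raw = np.power(2.0, vals)
    if config.mnar_steepness > 0:
        p_miss = 1.0 / (1.0 + np.exp(config.mnar_steepness * (vals - config.mnar_midpoint)))
        raw[rng.random(vals.shape) < p_miss] = np.nan
    if config.mcar_rate > 0:
        raw[rng.random(vals.shape) < config.mcar_rate] = np.nan
    return pd.DataFrame(raw, index=log2.index, columns=log2.columns)


def _clinical(config: SyntheticConfig, groups: pd.Series, rng: np.random.Generator) -> ClinicalTable:
    names = config.clinical_names()
    n = len(groups)
    cols: dict[str, np.ndarray] = {}
    panel = {pf.name: pf for pf in config.panel_spec}
    group_list = [g for g in GROUPS if g in config.group_sizes]
    for name in names:
        if name.startswith("BIN"):
            # binary indicator with group-specific prevalence
            probs = {g: rng.uniform(0.2, 0.8) for g in group_list}
            p = groups.map(probs).to_numpy(dtype=float)
            cols[name] = (rng.random(n) < p).astype(float)
            continue
        x = rng.standard_normal(n)
        if config.clinical_shift_sd > 0:
            shifts = {g: rng.normal(0.0, config.clinical_shift_sd) for g in group_list}
            x = x + groups.map(shifts).to_numpy(dtype=float)
        if name in panel:
            pf = panel[name]
            x = x + pf.signed_effect() * (groups == pf.target_group).to_numpy(dtype=float)
        cols[name] = x
    data = pd.DataFrame(cols, index=groups.index)
    if config.clinical_missing_rate > 0:
        mask = rng.random(data.shape) < config.clinical_missing_rate
        data = data.mask(mask)
    meta = pd.DataFrame(
        {
            "type": ["binary" if c.startswith("BIN") else "numeric" for c in data.columns],
            "excluded": False,
        },
        index=data.columns,
    )
    return ClinicalTable(data, meta)


def generate_cohort(config: SyntheticConfig, cohort: str = "discovery") -> CohortBundle:
    """Generate one cohort; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids, groups = _group_vector(config)
    log2 = _protein_log2(config, groups, rng)
    raw = _apply_missingness(log2, config, rng)
    clinical = _clinical(config, groups, rng)
    labels = pd.DataFrame({"group": groups, "cohort": cohort}, index=groups.index)
    return CohortBundle(ProteinMatrix(raw, state="raw"), clinical, labels)


def generate_external_cohort(
    config: SyntheticConfig, panel_effects_only: bool = False
) -> CohortBundle:
    """External-validation cohort; optionally only panel features carry signal."""
    if panel_effects_only:
        config = replace(config, clinical_shift_sd=0.0)
    return generate_cohort(config, cohort="external")


# ---------------------------------------------------------------------------
# presets

def _discovery_panel() -> tuple[PanelFeature, ...]:
    # 2 up- and 4 down-regulated proteins in the AT group
    return (
        PanelFeature("PROT0001", "AT", 2.0, "up"),
        PanelFeature("PROT0002", "AT", 2.0, "up"),
        PanelFeature("PROT0003", "AT", 2.0, "down"),
        PanelFeature("PROT0004", "AT", 2.0, "down"),
        PanelFeature("PROT0005", "AT", 2.2, "down"),
        PanelFeature("PROT0006", "AT", 2.2, "down"),
    )


def _paper_discovery() -> SyntheticConfig:
    return SyntheticConfig(
        group_sizes={"CTRL": 66, "DLP": 55, "AT": 60},
        n_proteins=300,
        n_clinical=20,
        n_binary_clinical=2,
        panel_spec=_discovery_panel()
        + (
            PanelFeature("CLIN01", "AT", 1.5, "up"),
            PanelFeature("CLIN02", "DLP", 1.5, "up"),
        ),
        cluster_spec=(ClusterSpec(("PROT0010", "PROT0011", "PROT0012"), 0.9),),
        mnar_steepness=1.0,
        mnar_midpoint=18.0,
        mcar_rate=0.02,
        clinical_missing_rate=0.05,
        clinical_shift_sd=0.4,
    )


def _paper_external() -> SyntheticConfig:
    return replace(
        _paper_discovery(),
        group_sizes={"CTRL": 19, "DLP": 24, "AT": 30},
        seed=DEFAULT_SEED + 1,
    )


def _split_signal() -> SyntheticConfig:
    """Signal split across modalities: clinical isolates CTRL, proteins isolate AT."""
    return SyntheticConfig(
        group_sizes={"CTRL": 20, "DLP": 20, "AT": 20},
        n_proteins=20,
        n_clinical=8,
        panel_spec=(
            PanelFeature("CLIN01", "CTRL", 2.5, "down"),
            PanelFeature("CLIN02", "CTRL", 2.5, "up"),
            PanelFeature("PROT0001", "AT", 2.5, "up"),
            PanelFeature("PROT0002", "AT", 2.5, "down"),
        ),
        clinical_missing_rate=0.02,
        mcar_rate=0.01,
    )


def _smoke() -> SyntheticConfig:
    return SyntheticConfig(
        group_sizes={"CTRL": 15, "DLP": 15, "AT": 15},
        n_proteins=40,
        n_clinical=8,
        panel_spec=(
            PanelFeature("PROT0001", "AT", 2.5, "up"),
            PanelFeature("PROT0002", "AT", 2.5, "down"),
            PanelFeature("CLIN01", "DLP", 2.0, "up"),
        ),
        mnar_steepness=1.0,
        mnar_midpoint=17.0,
        mcar_rate=0.02,
        clinical_missing_rate=0.05,
        clinical_shift_sd=0.3,
    )


PRESETS = {
    "paper_discovery": _paper_discovery,
    "paper_external": _paper_external,
    "split_signal": _split_signal,
    "smoke": _smoke,
}


def preset(name: str, seed: int | None = None) -> SyntheticConfig:
    """Look up a shipped scenario by name, optionally re-seeded."""
    try:
        config = PRESETS[name]()
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    if seed is not None:
        config = replace(config, seed=seed)
    return config
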