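"""Parameter registry, configuration parsing and validation.

Every kinetic and transport constant of the model lives in one validated
record, :class:`ParameterSet`.  Each entry carries a value, units, and a
source tag: ``literature`` for constants taken or reconstructed from
published in vitro work, ``provisional`` for order-of-magnitude defaults
documented in the methods note, ``calibrated`` for values produced by the
genetic-algorithm calibration, and ``user`` for config-file overrides.

Cytokine and debris concentrations are carried in opaque "model units"
(abbreviated ``mu``); cell concentrations are per mm² of healing region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

from callusim.geometry import ConfigurationError, DomainSpec

PHENOTYPES = ("M0", "M1", "M2", "PMN")

# Literature values reconstructed from the calibrated values and their
# printed percentage deviations (see derive_literature_from_calibrated).
_CALIBRATED = {
    "k_R_M0": (2.33e-2, 0.109),     # h^-1, +10.9%
    "k_p_M1": (1.07e-3, 0.285),     # min^-1, +28.5%
    "k_e_PMN": (2.71e-3, -0.186),   # min^-1, -18.6%
    "PMN_0": (984.38, -0.016),      # mm^-2 (model units), -1.6%
}


def derive_literature_from_calibrated(calibrated: float, percent_delta: float) -> float:
    """Back out a literature value from a calibrated one and its % deviation.

    ``percent_delta`` is the fractional deviation of the calibrated value
    relative to literature (+0.285 for "+28.5%"), so
    ``literature = calibrated / (1 + percent_delta)``.
    """
    if percent_delta <= -1.0:
        raise ValueError("percent delta must exceed -100%")
    return calibrated / (1.0 + percent_delta)


@dataclass(frozen=True)
class ParamDef:
    name: str
    default: float
    units: str
    group: str
    doc: str
    sensitivity: bool = False
    source: str = "provisional"
    probability_rate: bool = False  # rate * dt_cell must stay <= 1


def _lit(name: str) -> float:
    cal, delta = _CALIBRATED[name]
    return derive_literature_from_calibrated(cal, delta)


_DEFS: list[ParamDef] = [
    # --- recruitment & initial conditions -------------------------------
    ParamDef("k_R_M0", _lit("k_R_M0"), "h^-1", "recruitment",
             "maximum non-polarized macrophage recruitment ratio", True, "literature", False),
    ParamDef("k_R_PMN_factor", 1.0, "-", "recruitment",
             "PMN recruitment ratio as a multiple of k_R_M0", True),
    ParamDef("MPhi_max", 1000.0, "mm^-2", "recruitment",
             "maximal macrophage concentration in the healing region", True),
    ParamDef("PMN_0", _lit("PMN_0"), "mm^-2 (mu)", "recruitment",
             "initial neutrophil concentration, uniform in the healing region", True, "literature"),
    ParamDef("Db_0", 2000.0, "mu", "recruitment",
             "initial fracture-debris concentration, homogeneous per voxel", True),
    # --- phenotype-specific cell kinetics -------------------------------
    ParamDef("k_v_M0", 2.0, "um min^-1", "phenotype", "M0 migration speed", True),
    ParamDef("k_v_M1", 2.0, "um min^-1", "phenotype", "M1 migration speed", True),
    ParamDef("k_v_M2", 2.0, "um min^-1", "phenotype", "M2 migration speed", True),
    ParamDef("k_v_PMN", 5.0, "um min^-1", "phenotype", "PMN migration speed", True, "literature"),
    ParamDef("k_p_M0", 6.0e-4, "min^-1", "phenotype", "M0 proliferation probability", True,
             "provisional", True),
    ParamDef("k_p_M1", _lit("k_p_M1"), "min^-1", "phenotype", "M1 proliferation probability",
             True, "literature", True),
    ParamDef("k_p_M2", 4.0e-4, "min^-1", "phenotype", "M2 proliferation probability", True,
             "provisional", True),
    ParamDef("k_a0_M0", 3.0e-4, "min^-1", "phenotype", "M0 baseline apoptosis probability",
             True, "provisional", True),
    ParamDef("k_a0_M1", 5.0e-4, "min^-1", "phenotype", "M1 baseline apoptosis probability",
             True, "provisional", True),
    ParamDef("k_a0_M2", 3.0e-4, "min^-1", "phenotype", "M2 baseline apoptosis probability",
             True, "provisional", True),
    ParamDef("k_a0_PMN", 5.0e-4, "min^-1", "phenotype",
             "PMN baseline apoptosis probability (short-lived first responders)",
             True, "provisional", True),
    ParamDef("k_e_M0", 5.0e-3, "min^-1", "phenotype", "M0 debris engulfment ratio", True),
    ParamDef("k_e_M1", 5.0e-3, "min^-1", "phenotype", "M1 debris engulfment ratio", True),
    ParamDef("k_e_M2", 5.0e-3, "min^-1", "phenotype", "M2 debris engulfment ratio", True),
    ParamDef("k_e_PMN", _lit("k_e_PMN"), "min^-1", "phenotype", "PMN debris engulfment ratio",
             True, "literature"),
    # --- polarization ----------------------------------------------------
    ParamDef("k01", 1.5e-3, "min^-1", "polarization", "M0→M1 polarization ratio", True,
             "provisional", True),
    ParamDef("k02", 7.0e-4, "min^-1", "polarization", "M0→M2 polarization ratio", True,
             "provisional", True),
    ParamDef("k12", 5.0e-4, "min^-1", "polarization", "M1→M2 interpolarization ratio", True,
             "provisional", True),
    ParamDef("k21", 5.0e-5, "min^-1", "polarization",
             "M2→M1 interpolarization ratio (rare by design)", True, "provisional", True),
    ParamDef("a01", 0.3, "mu", "polarization", "TNFα half-saturation for M0→M1", True),
    ParamDef("a02", 0.3, "mu", "polarization", "IL10 half-saturation for M0→M2", True),
    ParamDef("a12", 0.3, "mu", "polarization", "IL10 half-saturation for M1→M2", True),
    ParamDef("a21", 0.3, "mu", "polarization", "TNFα half-saturation for M2→M1", True),
    # --- apoptosis modulation -------------------------------------------
    ParamDef("alpha_d", 1.0e-4, "mu^-1", "apoptosis",
             "apoptosis increase per unit phagocytosed debris load", True),
    ParamDef("alpha_n", 1.0e-1, "cell^-1", "apoptosis",
             "apoptosis increase per neighbouring cell (crowding)", True),
    # --- secretion (Table-style cell sources) ---------------------------
    ParamDef("k_TNF", 5.0e-2, "mu min^-1", "secretion", "TNFα base secretion rate", True),
    ParamDef("k_TNI", 1.0, "-", "secretion", "IFNγ amplification gain on TNFα secretion", True),
    ParamDef("a_TNI", 1.0, "mu", "secretion", "IFNγ sigmoid midpoint for TNFα amplification"),
    ParamDef("k_TNIL", 0.8, "-", "secretion", "IL10-sensitive share of M1 TNFα secretion"),
    ParamDef("a_TNIL", 2.0, "mu^-1", "secretion", "IL10 inhibition steepness on M1 TNFα"),
    ParamDef("b_TNIL", 0.2, "-", "secretion", "IL10-insensitive floor of M1 TNFα secretion"),
    ParamDef("k_TNTG", 0.8, "-", "secretion", "TGFβ-sensitive share of M1 TNFα secretion"),
    ParamDef("a_TNTG", 2.0, "mu^-1", "secretion", "TGFβ inhibition steepness on M1 TNFα"),
    ParamDef("b_TNTG", 0.2, "-", "secretion", "TGFβ-insensitive floor of M1 TNFα secretion"),
    ParamDef("k_IL10", 2.0e-2, "mu min^-1", "secretion", "IL10 secretion rate (M0, M2)", True),
    ParamDef("k_TGF", 2.0e-2, "mu min^-1", "secretion", "TGFβ secretion rate (M0, M1, M2)", True),
    ParamDef("k_IFN", 1.0e-2, "mu min^-1", "secretion", "IFNγ base secretion rate", True),
    ParamDef("a_ITN", 1.0, "mu^-1", "secretion", "TNFα inhibition steepness on IFNγ secretion",
             True),
    # --- transport -------------------------------------------------------
    ParamDef("D_tnfa", 20.0, "um^2 s^-1", "transport", "TNFα diffusion coefficient"),
    ParamDef("D_il10", 20.0, "um^2 s^-1", "transport", "IL10 diffusion coefficient"),
    ParamDef("D_tgfb", 20.0, "um^2 s^-1", "transport", "TGFβ diffusion coefficient"),
    ParamDef("D_ifng", 20.0, "um^2 s^-1", "transport", "IFNγ diffusion coefficient"),
    ParamDef("d_tnfa", 2.0e-4, "s^-1", "transport", "TNFα decay rate"),
    ParamDef("d_il10", 1.0e-4, "s^-1", "transport", "IL10 decay rate"),
    ParamDef("d_tgfb", 1.0e-4, "s^-1", "transport", "TGFβ decay rate"),
    ParamDef("d_ifng", 2.0e-4, "s^-1", "transport", "IFNγ decay rate"),
    # --- scales & occupancy ---------------------------------------------
    ParamDef("dt_cell", 1.0, "min", "scales", "cellular-clock time step"),
    ParamDef("dt_mol", 1.0, "s", "scales", "molecular-clock time step"),
    ParamDef("r_ex", 7.5, "um", "scales",
             "hard exclusion radius between cell centres (≈ half a macrophage diameter)"),
    ParamDef("r_neighbor", 30.0, "um", "scales", "crowding-count radius for apoptosis"),
    ParamDef("engulf_radius", 1, "voxel", "scales",
             "engulfment stencil: 0 = own voxel, 1 = plus 4-neighbours"),
    ParamDef("chemotaxis_range", 40.0, "um", "scales",
             "Gaussian sensing range of the debris chemoattractant signal"),
]

REGISTRY: dict[str, ParamDef] = {d.name: d for d in _DEFS}
SENSITIVITY_PARAMETERS: tuple[str, ...] = tuple(d.name for d in _DEFS if d.sensitivity)

# Calibrated overrides reported by the genetic-algorithm calibration.
CALIBRATED_VALUES: dict[str, float] = {k: v[0] for k, v in _CALIBRATED.items()}


class ParameterSet:
    """Validated bag of all model parameters with per-entry source tags."""

    __slots__ = ("_values", "_sources")

    def __init__(self, overrides: Mapping[str, float] | None = None,
                 source: str = "user") -> None:
        self._values = {d.name: d.default for d in _DEFS}
        self._sources = {d.name: d.source for d in _DEFS}
        if overrides:
            for key, val in overrides.items():
                self._set(key, val, source)
        self.validate()

    # -- mapping-ish access ------------------------------------------------
    def _set(self, key: str, value: float, source: str) -> None:
        if key not in self._values:
            raise ConfigurationError(f"unknown parameter: {key!r}")
        self._values[key] = float(value)
        self._sources[key] = source

    def __getattr__(self, key: str) -> float:
        try:
            return self._values[key]
        except KeyError:
            raise AttributeError(key) from None

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def source_of(self, key: str) -> str:
        return self._sources[key]

    def replace(self, source: str = "user", **overrides: float) -> "ParameterSet":
        new = ParameterSet()
        new._values = dict(self._values)
        new._sources = dict(self._sources)
        for key, val in overrides.items():
            new._set(key, val, source)
        new.validate()
        return new

    def per_phenotype(self, stem: str) -> dict[str, float]:
        """e.g. ``per_phenotype('k_v') -> {'M0': ..., 'PMN': ...}`` (k_p(PMN)=0)."""
        out = {}
        for ph in PHENOTYPES:
            key = f"{stem}_{ph}"
            out[ph] = self._values.get(key, 0.0)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        dt_cell = self._values["dt_cell"]
        bad = [k for k, v in self._values.items() if not math.isfinite(v) or v < 0]
        if bad:
            raise ConfigurationError(f"parameters must be finite and >= 0: {bad}")
        if self._values["MPhi_max"] <= 0:
            raise ConfigurationError("MPhi_max must be positive")
        for d in _DEFS:
            if d.probability_rate and self._values[d.name] * dt_cell > 1.0:
                raise ConfigurationError(
                    f"{d.name} * dt_cell exceeds 1 (not a probability per step)")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def to_records(self) -> list[dict[str, Any]]:
        return [
            {"name": d.name, "value": self._values[d.name], "units": d.units,
             "group": d.group, "source": self._sources[d.name],
             "sensitivity": d.sensitivity, "doc": d.doc}
            for d in _DEFS
        ]

    @classmethod
    def literature(cls) -> "ParameterSet":
        """The literature/provisional default set (no calibration applied)."""
        return cls()

    @classmethod
    def calibrated(cls) -> "ParameterSet":
        """Defaults with the four GA-calibrated values applied."""
        return cls().replace(source="calibrated", **CALIBRATED_VALUES)


@dataclass(frozen=True)
class RunOptions:
    """Non-physical run controls."""

    days: float = 3.0
    seed: int = 0
    n_replicates: int = 5
    record_every_min: float = 60.0
    chemotaxis: bool = True
    chemotaxis_softmax: bool = False  # softmax-weighted ascent instead of deterministic

    def __post_init__(self) -> None:
        if self.days <= 0 or self.days > 5:
            raise ConfigurationError("simulated horizon must be in (0, 5] days")
        if self.record_every_min <= 0:
            raise ConfigurationError("record_every_min must be positive")


_DOMAIN_KEYS = {
    "gap_width", "cortex_thickness", "bone_outer_radius", "callus_semi_axes",
    "mol_resolution", "cell_resolution", "extent", "quarter",
}
_RUN_KEYS = {"days", "seed", "n_replicates", "record_every_min", "chemotaxis",
             "chemotaxis_softmax"}


def load_config(path: str | Path) -> tuple[DomainSpec, ParameterSet, RunOptions]:
    """Parse a YAML config into validated domain/parameter/run objects.

    Schema: three optional top-level maps ``domain``, ``parameters``, ``run``.
    Unknown keys anywhere are rejected.  An empty file yields the full
    literature-default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - {"domain", "parameters", "run"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    dom_raw = dict(raw.get("domain") or {})
    bad = set(dom_raw) - _DOMAIN_KEYS
    if bad:
        raise ConfigurationError(f"unknown domain keys: {sorted(bad)}")
    if "callus_semi_axes" in dom_raw:
        dom_raw["callus_semi_axes"] = tuple(dom_raw["callus_semi_axes"])
    spec = DomainSpec(**dom_raw)

    par_raw = raw.get("parameters") or {}
    params = ParameterSet(par_raw, source="user")

    run_raw = dict(raw.get("run") or {})
    bad = set(run_raw) - _RUN_KEYS
    if bad:
        raise ConfigurationError(f"unknown run keys: {sorted(bad)}")
    opts = RunOptions(**run_raw)
    return spec, params, opts


def dump_config(spec: DomainSpec, params: ParameterSet, opts: RunOptions,
                path: str | Path) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    doc = {
        "domain": {
            "gap_width": spec.gap_width,
            "cortex_thickness": spec.cortex_thickness,
            "bone_outer_radius": spec.bone_outer_radius,
            "callus_semi_axes": list(spec.callus_semi_axes),
            "mol_resolution": spec.mol_resolution,
            "cell_resolution": spec.cell_resolution,
            "extent": spec.extent,
            "quarter": spec.quarter,
        },
        "parameters": params.to_dict(),
        "run": {
            "days": opts.days,
            "seed": opts.seed,
            "n_replicates": opts.n_replicates,
            "record_every_min": opts.record_every_min,
            "chemotaxis": opts.chemotaxis,
            "chemotaxis_softmax": opts.chemotaxis_softmax,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
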