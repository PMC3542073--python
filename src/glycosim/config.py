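"""Reactor and enzyme-profile configuration.

The packaged reference configuration describes the default study
conditions: seeds and inlet split, mass cutoff and pruning threshold,
compartment residence times and volumes, donor concentrations, enzyme
activities and localization.  All values can be overridden from a user
YAML file of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .rules import load_rule_table

__all__ = ["ReactorConfig", "EnzymeProfile", "load_reference_config",
           "kf_base_by_enzyme", "ENZYMES"]


def kf_base_by_enzyme() -> dict[str, float]:
    """Base forward-rate coefficient per enzyme (its first-listed rule)."""
    out: dict[str, float] = {}
    for rule in load_rule_table():
        out.setdefault(rule.enzyme, rule.kf)
    return out


def _enzyme_order() -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for rule in load_rule_table():
        seen.setdefault(rule.enzyme)
    return tuple(seen)


ENZYMES = _enzyme_order()


@dataclass
class ReactorConfig:
    """Well-mixed 4-compartment Golgi cascade parameters."""

    tau: np.ndarray                      # residence times, min
    volumes: np.ndarray                  # volume fractions
    c_tot: float                         # total glycan concentration, uM
    inlet: dict[str, float]              # seed structure -> fraction
    donors: dict[str, float]             # donor species -> concentration, uM

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.tau <= 0):
            raise ValueError("residence times must be positive")
        if self.c_tot <= 0:
            raise ValueError("c_tot must be positive")
        s = sum(self.inlet.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"inlet fractions sum to {s}, expected 1")

    @property
    def n_compartments(self) -> int:
        return len(self.tau)


@dataclass
class EnzymeProfile:
    """Enzyme activity levels and Golgi localization.

    ``activity`` is the reported per-enzyme activity in min^-1, defined as
    kf_base * Et_total / c_tot.  ``localization`` rows are the fraction of
    each enzyme's total residing in each compartment.
    """

    activity: dict[str, float]
    localization: dict[str, list[float]]
    c_tot: float = 10.0
    kf_base: dict[str, float] | None = None   # overrides the rule-table kf

    def __post_init__(self):
        for enz, row in self.localization.items():
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"localization of {enz} does not sum to 1")
        for enz, a in self.activity.items():
            if a < 0:
                raise ValueError(f"negative activity for {enz}")

    def _kf(self, enzyme: str) -> float:
        if self.kf_base and enzyme in self.kf_base:
            return self.kf_base[enzyme]
        return kf_base_by_enzyme()[enzyme]

    def et_total(self, enzyme: str) -> float:
        """Total enzyme concentration (uM) implied by the activity."""
        return self.activity.get(enzyme, 0.0) * self.c_tot / self._kf(enzyme)

    def et_matrix(self, enzymes: list[str], volumes: np.ndarray) -> np.ndarray:
        """Concentration of each enzyme in each compartment (uM)."""
        n_c = len(volumes)
        out = np.zeros((len(enzymes), n_c))
        for i, enz in enumerate(enzymes):
            loc = np.asarray(self.localization[enz], dtype=float)
            out[i] = self.et_total(enz) * loc / np.asarray(volumes, dtype=float)
        return out

    def scaled(self, factors: dict[str, float]) -> "EnzymeProfile":
        act = dict(self.activity)
        for enz, f in factors.items():
            act[enz] = act.get(enz, 0.0) * f
        return EnzymeProfile(act, self.localization, self.c_tot, self.kf_base)

    def with_activity(self, updates: dict[str, float]) -> "EnzymeProfile":
        act = dict(self.activity)
        act.update(updates)
        return EnzymeProfile(act, self.localization, self.c_tot, self.kf_base)


@dataclass
class ReferenceConfig:
    seeds: list[str]
    mass_cutoff: float
    pruning_enabled: bool
    prune_threshold: float
    generation_activity_floor: float
    mass_range: tuple[float, float]
    reactor: ReactorConfig
    enzymes: EnzymeProfile
    raw: dict = field(default_factory=dict)


def load_reference_config(path: str | None = None) -> ReferenceConfig:
    """Load the packaged reference configuration (or a user override)."""
    if path is None:
        text = resources.files("glycosim.data").joinpath(
            "reference_config.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    reactor = ReactorConfig(
        tau=doc["reactor"]["tau"],
        volumes=doc["reactor"]["volumes"],
        c_tot=float(doc["reactor"]["c_tot"]),
        inlet=doc["inlet"],
        donors={k: float(v) for k, v in doc["reactor"]["donors"].items()},
    )
    enzymes = EnzymeProfile(
        activity={k: float(v) for k, v in doc["enzymes"].items()},
        localization=doc["localization"],
        c_tot=reactor.c_tot,
    )
    return ReferenceConfig(
        seeds=list(doc["seeds"]),
        mass_cutoff=float(doc["mass_cutoff"]),
        pruning_enabled=bool(doc["pruning_enabled"]),
        prune_threshold=float(doc["prune_threshold"]),
        generation_activity_floor=float(doc.get("generation_activity_floor", 0.0)),
        mass_range=tuple(doc.get("mass_range", [1400.0, 4000.0])),
        reactor=reactor,
        enzymes=enzymes,
        raw=doc,
    )
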