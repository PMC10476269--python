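"""Cleavable cross-linker chemistry.

An MS-cleavable cross-linker breaks apart during MS2 fragmentation, leaving
one of two remnant "arm" fragments on each peptide. A cross-linked peptide
therefore shows up as a *doublet*: two MS2 peaks separated by the mass
difference of the long and short arm, which is specific to the reagent
(DSSO: 31.9721 Da, DSBSO: 182.0071 Da).

Built-in definitions for DSSO and DSBSO encode the sulfoxide cleavage
chemistry: the short arm is the alkene remnant (C3H2O), the long arm the
sulfur-containing remnant (thiol C3H2OS for DSSO). Both reagents are
NHS esters reacting with lysine side chains and protein N-termini.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from pyteomics import mass as _pmass

__all__ = [
    "ArmFragment",
    "CrosslinkerProduct",
    "CrosslinkerSpec",
    "mass_from_composition",
    "doublet_delta",
    "load_spec",
    "save_spec",
    "builtin_names",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def mass_from_composition(formula: str) -> float:
    """Monoisotopic mass (Da) of an elemental formula such as ``"C3H2OS"``.

    The empty formula has mass 0. Unknown element symbols raise ``ValueError``.
    """
    if not formula:
        return 0.0
    pos = 0
    comp: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        elem, count = m.group(1), int(m.group(2) or 1)
        if elem not in _pmass.nist_mass:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        comp[elem] = comp.get(elem, 0) + count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return _pmass.calculate_mass(composition=_pmass.Composition(comp))


@dataclass(frozen=True)
class ArmFragment:
    """One cleavage remnant of the cross-linker left on a peptide."""

    label: str  # "short" | "long"
    composition: str  # elemental formula, may be empty if only mass known
    mono_mass: float

    def __post_init__(self) -> None:
        if self.label not in ("short", "long"):
            raise ValueError(f"arm label must be 'short' or 'long', got {self.label!r}")
        if self.composition:
            calc = mass_from_composition(self.composition)
            if abs(calc - self.mono_mass) > 1e-4:
                raise ValueError(
                    f"{self.label} arm mass {self.mono_mass} does not match "
                    f"composition {self.composition} ({calc:.5f})"
                )


@dataclass(frozen=True)
class CrosslinkerProduct:
    """An alternative cleavage or loss the remnant fragment may undergo.

    ``delta_mass`` is added to the nominal arm mass (a water loss is
    -18.0106).
    """

    label: str
    delta_mass: float
    applies_to: str = "both"  # "short" | "long" | "both"

    def __post_init__(self) -> None:
        if abs(self.delta_mass) >= 500:
            raise ValueError(f"implausible product delta {self.delta_mass}")
        if self.applies_to not in ("short", "long", "both"):
            raise ValueError(f"applies_to must be short/long/both, got {self.applies_to!r}")


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Full chemistry of one cleavable cross-linker."""

    name: str
    reactive_residues: frozenset[str]
    protein_nterm_reactive: bool
    short_arm: ArmFragment
    long_arm: ArmFragment
    products: tuple[CrosslinkerProduct, ...] = ()
    intact_mass: float = 0.0  # mass added to the peptide pair by the intact link

    def __post_init__(self) -> None:
        if not self.reactive_residues and not self.protein_nterm_reactive:
            raise ValueError("cross-linker has no reactive sites")
        if self.long_arm.mono_mass <= self.short_arm.mono_mass:
            raise ValueError("long arm must be heavier than short arm")

    def arm_mass(self, arm: str) -> float:
        """Remnant mass for ``arm`` given as 'light'/'short' or 'heavy'/'long'."""
        if arm in ("light", "short"):
            return self.short_arm.mono_mass
        if arm in ("heavy", "long"):
            return self.long_arm.mono_mass
        raise ValueError(f"unknown arm {arm!r}")

    def products_for(self, arm: str) -> list[CrosslinkerProduct | None]:
        """Product variants applicable to an arm; ``None`` = unchanged remnant."""
        side = "short" if arm in ("light", "short") else "long"
        out: list[CrosslinkerProduct | None] = [None]
        out.extend(p for p in self.products if p.applies_to in (side, "both"))
        return out


def doublet_delta(spec: CrosslinkerSpec) -> float:
    """Cross-linker-specific doublet mass difference: long minus short arm."""
    return spec.long_arm.mono_mass - spec.short_arm.mono_mass


# ---------------------------------------------------------------------------
# Built-ins.
#
# DSSO cleaves at either C-S bond of its central sulfoxide, leaving an alkene
# (C3H2O) or a thiol (C3H2OS) remnant; the intact link adds C6H6O3S.
# DSBSO (azide-tagged disuccinimidyl bis-sulfoxide) likewise leaves the
# alkene remnant or the heavy sulfoxide-containing remnant C8H12O4S2.

_BUILTINS: dict[str, dict] = {
    "DSSO": {
        "name": "DSSO",
        "reactive_residues": "K",
        "nterm": True,
        "short_arm": {"composition": "C3H2O"},
        "long_arm": {"composition": "C3H2OS"},
        "intact_composition": "C6H6O3S",
        "products": [],
        # Alternative cleavage products (sulfenic-acid remnant, water loss)
        # can be enabled by adding entries like
        #   {label: water_loss, delta_mass: -18.010565, applies_to: both}
    },
    "DSBSO": {
        "name": "DSBSO",
        "reactive_residues": "K",
        "nterm": True,
        "short_arm": {"composition": "C3H2O"},
        "long_arm": {"composition": "C8H12O4S2"},
        "intact_composition": "C11H16O6S2",
        "products": [],
    },
}


def builtin_names() -> list[str]:
    return sorted(_BUILTINS)


def _arm_from_config(label: str, cfg: dict) -> ArmFragment:
    comp = cfg.get("composition", "")
    mono = cfg.get("mono_mass")
    if mono is None:
        if not comp:
            raise ValueError(f"{label} arm needs a composition or mono_mass")
        mono = mass_from_composition(comp)
    return ArmFragment(label=label, composition=comp, mono_mass=float(mono))


def _spec_from_dict(cfg: dict) -> CrosslinkerSpec:
    short = _arm_from_config("short", cfg["short_arm"])
    long = _arm_from_config("long", cfg["long_arm"])
    products = tuple(
        CrosslinkerProduct(
            label=p["label"],
            delta_mass=float(p["delta_mass"]),
            applies_to=p.get("applies_to", "both"),
        )
        for p in cfg.get("products", []) or []
    )
    intact = cfg.get("intact_mass")
    if intact is None:
        comp = cfg.get("intact_composition", "")
        # sulfoxide chemistry: intact link = both remnants + water
        intact = mass_from_composition(comp) if comp else (
            short.mono_mass + long.mono_mass + 18.010565
        )
    return CrosslinkerSpec(
        name=str(cfg["name"]),
        reactive_residues=frozenset(cfg.get("reactive_residues", "")),
        protein_nterm_reactive=bool(cfg.get("nterm", False)),
        short_arm=short,
        long_arm=long,
        products=products,
        intact_mass=float(intact),
    )


def load_spec(source: str | Path | dict) -> CrosslinkerSpec:
    """Load a cross-linker definition.

    ``source`` may be a built-in name ("DSSO", "DSBSO"), a path to a YAML
    config file, or an already-parsed mapping. Validation rejects definitions
    whose long arm is not heavier than the short arm or that have no reactive
    site.
    """
    if isinstance(source, dict):
        return _spec_from_dict(source)
    name = str(source)
    if name.upper() in _BUILTINS:
        return _spec_from_dict(_BUILTINS[name.upper()])
    path = Path(name)
    if not path.exists():
        raise ValueError(
            f"unknown cross-linker {name!r}: not a built-in "
            f"({', '.join(builtin_names())}) and not a config file"
        )
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _spec_from_dict(cfg)


def save_spec(spec: CrosslinkerSpec, path: str | Path) -> None:
    """Serialize a spec to YAML such that ``load_spec`` round-trips it."""
    cfg = {
        "name": spec.name,
        "reactive_residues": "".join(sorted(spec.reactive_residues)),
        "nterm": spec.protein_nterm_reactive,
        "short_arm": {
            "composition": spec.short_arm.composition,
            "mono_mass": spec.short_arm.mono_mass,
        },
        "long_arm": {
            "composition": spec.long_arm.composition,
            "mono_mass": spec.long_arm.mono_mass,
        },
        "products": [
            {"label": p.label, "delta_mass": p.delta_mass, "applies_to": p.applies_to}
            for p in spec.products
        ],
        "intact_mass": spec.intact_mass,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
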