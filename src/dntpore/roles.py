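"""Semantic particle roles and name-mapping dialects.

Analyses in this package never look at raw atom/bead names; every particle
carries one semantic role (DNA backbone, lipid phosphate, sodium ion, ...).
A :class:`RoleDialect` translates the ``(residue name, atom name)`` pairs of
an input structure into roles, chain positions and probe radii.  Two dialects
ship with the package: ``cg-martini`` for coarse-grained MARTINI-style beads
and ``at-charmm-like`` for atomistic nucleic-acid/phospholipid naming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import yaml


class Role(str, Enum):
    """Semantic particle classes consumed by the analysis modules."""

    DNA_BB = "DNA_BB"
    DNA_BASE = "DNA_BASE"
    ETHYL = "ETHYL"
    LIPID_NC3 = "LIPID_NC3"
    LIPID_PO4 = "LIPID_PO4"
    LIPID_GLY = "LIPID_GLY"
    LIPID_TAIL_SN1 = "LIPID_TAIL_SN1"
    LIPID_TAIL_SN2 = "LIPID_TAIL_SN2"
    WATER = "WATER"
    ION_NA = "ION_NA"
    ION_CL = "ION_CL"
    OTHER = "OTHER"


#: Roles that belong to the DNA nanotube itself.
DNT_ROLES = frozenset({Role.DNA_BB, Role.DNA_BASE, Role.ETHYL})
#: Roles that belong to a lipid molecule.
LIPID_ROLES = frozenset(
    {Role.LIPID_NC3, Role.LIPID_PO4, Role.LIPID_GLY,
     Role.LIPID_TAIL_SN1, Role.LIPID_TAIL_SN2}
)
ION_ROLES = frozenset({Role.ION_NA, Role.ION_CL})


class UnknownNamesError(ValueError):
    """Raised when a dialect cannot map every name in a structure."""

    def __init__(self, unknown: list[tuple[str, str]]):
        self.unknown = sorted(set(unknown))
        listing = ", ".join(f"{r}/{a}" for r, a in self.unknown[:20])
        more = "" if len(self.unknown) <= 20 else f" (+{len(self.unknown) - 20} more)"
        super().__init__(
            f"dialect cannot map {len(self.unknown)} residue/atom name pair(s): "
            f"{listing}{more}"
        )


@dataclass
class RoleAssignment:
    """Resolved mapping for a single particle."""

    role: Role
    tail_position: Optional[int] = None
    bead_radius: Optional[float] = None  # nm


@dataclass
class RoleDialect:
    """Maps ``(residue name, atom name)`` to a :class:`RoleAssignment`.

    ``residues`` holds exact atom-name entries per residue name; a residue may
    additionally carry ``_patterns``, an ordered list of ``(regex, spec)``
    pairs tried when no exact entry matches.  ``radii`` supplies probe radii
    (nm) for pore profiling, keyed by radius class; specs may name a class via
    ``radius_class`` or give an explicit ``bead_radius``.
    """

    name: str
    residues: dict[str, dict]
    radii: dict[str, float] = field(default_factory=dict)

    def _resolve_spec(self, spec) -> RoleAssignment:
        if isinstance(spec, str):
            spec = {"role": spec}
        role = Role(spec["role"])
        radius = spec.get("bead_radius")
        if radius is None:
            cls = spec.get("radius_class", "default")
            radius = self.radii.get(cls, self.radii.get("default"))
        return RoleAssignment(
            role=role,
            tail_position=spec.get("tail_position"),
            bead_radius=radius,
        )

    def lookup(self, resname: str, atomname: str) -> Optional[RoleAssignment]:
        entry = self.residues.get(resname)
        if entry is None:
            entry = self.residues.get("*")
        if entry is None:
            return None
        spec = entry.get(atomname)
        if spec is None:
            for pattern, pspec in entry.get("_patterns", []):
                if re.match(pattern, atomname):
                    spec = pspec
                    break
        if spec is None:
            return None
        return self._resolve_spec(spec)

    def assign(
        self,
        resnames,
        atomnames,
        on_unknown: str = "error",
    ) -> list[RoleAssignment]:
        """Map parallel name arrays; ``on_unknown`` is ``error`` or ``other``."""
        out: list[RoleAssignment] = []
        unknown: list[tuple[str, str]] = []
        fallback = RoleAssignment(Role.OTHER, bead_radius=self.radii.get("default", 0.26))
        for rn, an in zip(resnames, atomnames):
            hit = self.lookup(rn, an)
            if hit is None:
                unknown.append((rn, an))
                out.append(fallback)
            else:
                out.append(hit)
        if unknown and on_unknown == "error":
            raise UnknownNamesError(unknown)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RoleDialect":
        residues = {}
        for resname, entry in data.get("residues", {}).items():
            parsed = {}
            patterns = []
            for key, spec in entry.items():
                if key == "_patterns":
                    patterns = [(p["match"], p) for p in spec]
                else:
                    parsed[key] = spec
            if patterns:
                parsed["_patterns"] = patterns
            residues[resname] = parsed
        return cls(
            name=data["name"],
            residues=residues,
            radii=dict(data.get("radii", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RoleDialect":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def builtin_dialect(name: str) -> RoleDialect:
    """Load a packaged dialect (``cg-martini`` or ``at-charmm-like``)."""
    ref = resources.files("dntpore") / "dialects" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        available = [p.name[:-5] for p in (resources.files("dntpore") / "dialects").iterdir()]
        raise KeyError(f"no built-in dialect {name!r}; available: {sorted(available)}")
    return RoleDialect.from_dict(yaml.safe_load(text))
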