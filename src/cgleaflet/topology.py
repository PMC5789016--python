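"""Lipid species registry: which beads play which role.

Every analysis in this package locates a lipid by a single *reference
phosphate* bead (density, thickness and order maps all bin on it) and walks
ordered *tail chains* of bead names to form bond vectors.  The registry maps
a residue name, as found in a GRO file, to those roles.

The shipped defaults follow MARTINI-style bead naming for POPE, POPG and
cardiolipin, plus a generic large-headgroup LPS-like species with a
configurable number of sugar beads and tails.  Cardiolipin carries two
phosphate moieties; its reference bead defaults to the central glycerol
linker (``GL0``) so that exactly one bead per lipid enters the maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "LipidSpecies",
    "LipidTopology",
    "TopologyError",
    "default_topology",
    "lps_species",
]


class TopologyError(ValueError):
    """Raised for inconsistent species definitions."""


@dataclass(frozen=True)
class LipidSpecies:
    """Bead roles of one lipid species.

    Parameters
    ----------
    name:
        Residue name as written to / read from coordinate files.
    ref_bead:
        The single reference bead (normally the phosphate) used to
        position the lipid in 2D maps and leaflet assignment.
    head_beads, linker_beads:
        Headgroup and glycerol-linker bead names, ordered from the
        solvent side inward.
    tail_chains:
        One ordered bead-name list per acyl tail; consecutive names form
        the bond vectors of the order parameter.
    charge:
        Net bead charge of the whole lipid (for counter-ion counting).
    """

    name: str
    ref_bead: str
    head_beads: tuple[str, ...] = ()
    linker_beads: tuple[str, ...] = ()
    tail_chains: tuple[tuple[str, ...], ...] = ()
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.ref_bead:
            raise TopologyError(f"{self.name}: a reference bead is required")
        for chain in self.tail_chains:
            if len(chain) < 2:
                raise TopologyError(
                    f"{self.name}: tail chain {chain!r} has fewer than 2 beads"
                )
        all_beads = self.bead_order()
        if len(set(all_beads)) != len(all_beads):
            raise TopologyError(f"{self.name}: duplicate bead names in species")

    def bead_order(self) -> tuple[str, ...]:
        """Canonical per-residue bead ordering used by the generator."""
        tails = tuple(b for chain in self.tail_chains for b in chain)
        return self.head_beads + (self.ref_bead,) + self.linker_beads + tails

    @property
    def n_beads(self) -> int:
        return len(self.bead_order())

    @property
    def tail_bead_names(self) -> tuple[str, ...]:
        return tuple(b for chain in self.tail_chains for b in chain)


def _tail(letter: str, n_beads: int) -> tuple[str, ...]:
    return tuple(f"C{k + 1}{letter}" for k in range(n_beads))


def lps_species(
    n_tails: int = 6, n_head: int = 8, tail_beads: int = 4, name: str = "LPS"
) -> LipidSpecies:
    """A generic LPS-like species: large sugar headgroup, many tails.

    The tail count is exposed as a parameter (default 6) because CG LPS
    models vary; the analysis only needs bead roles, not chemistry.
    """
    if n_tails < 1 or n_tails > 26:
        raise TopologyError("LPS tail count must be in 1..26")
    letters = [chr(ord("A") + i) for i in range(n_tails)]
    return LipidSpecies(
        name=name,
        ref_bead="PO1",
        head_beads=tuple(f"S{j + 1:02d}" for j in range(n_head)),
        linker_beads=("GM1", "GM2"),
        tail_chains=tuple(_tail(c, tail_beads) for c in letters),
        charge=-1,
    )


def _pope() -> LipidSpecies:
    return LipidSpecies(
        name="POPE",
        ref_bead="PO4",
        head_beads=("NH3",),
        linker_beads=("GL1", "GL2"),
        tail_chains=(_tail("A", 4), _tail("B", 4)),
        charge=0,
    )


def _popg() -> LipidSpecies:
    return LipidSpecies(
        name="POPG",
        ref_bead="PO4",
        head_beads=("GL0",),
        linker_beads=("GL1", "GL2"),
        tail_chains=(_tail("A", 4), _tail("B", 4)),
        charge=-1,
    )


def _cardiolipin() -> LipidSpecies:
    # Two phosphates (PO41/PO42); the central linking bead GL0 is the
    # designated single reference bead.
    return LipidSpecies(
        name="CDL",
        ref_bead="GL0",
        head_beads=("PO41", "PO42"),
        linker_beads=("GL1", "GL2", "GL3", "GL4"),
        tail_chains=(_tail("A", 4), _tail("B", 4), _tail("C", 4), _tail("D", 4)),
        charge=-2,
    )


# Residue names treated as solvent / ions rather than lipids.
SOLVENT_RESNAMES = frozenset({"W", "WF", "ION"})
PROTEIN_RESNAMES = frozenset({"PROT"})


@dataclass
class LipidTopology:
    """Registry of lipid species keyed by residue name."""

    species: dict[str, LipidSpecies] = field(default_factory=dict)

    def add(self, sp: LipidSpecies) -> None:
        self.species[sp.name] = sp

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def __getitem__(self, name: str) -> LipidSpecies:
        try:
            return self.species[name]
        except KeyError:
            raise TopologyError(f"unknown lipid species {name!r}") from None

    def names(self) -> tuple[str, ...]:
        return tuple(self.species)

    def is_lipid(self, resname: str) -> bool:
        return resname in self.species

    # ---- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            name: {
                "ref_bead": sp.ref_bead,
                "head_beads": list(sp.head_beads),
                "linker_beads": list(sp.linker_beads),
                "tail_chains": [list(c) for c in sp.tail_chains],
                "charge": sp.charge,
            }
            for name, sp in self.species.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "LipidTopology":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise TopologyError(f"{path}: topology file must map species to roles")
        topo = cls()
        for name, spec in doc.items():
            topo.add(
                LipidSpecies(
                    name=name,
                    ref_bead=spec["ref_bead"],
                    head_beads=tuple(spec.get("head_beads", ())),
                    linker_beads=tuple(spec.get("linker_beads", ())),
                    tail_chains=tuple(tuple(c) for c in spec.get("tail_chains", ())),
                    charge=int(spec.get("charge", 0)),
                )
            )
        return topo


def default_topology(
    lps_n_tails: int = 6, lps_n_head: int = 8, tail_beads: int = 4
) -> LipidTopology:
    """Registry with shipped defaults: POPE, POPG, cardiolipin, LPS-like."""
    topo = LipidTopology()
    for sp in (
        _pope(),
        _popg(),
        _cardiolipin(),
        lps_species(lps_n_tails, lps_n_head, tail_beads),
    ):
        topo.add(sp)
    return topo
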