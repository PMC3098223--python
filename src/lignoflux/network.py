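"""Monolignol pathway topology for alfalfa stems.

The model covers the route from phenylalanine to the three hydroxycinnamyl
alcohols that are exported to the cell wall as p-hydroxyphenyl (H), guaiacyl
(G) and syringyl (S) lignin monomers.  Two features distinguish it from the
textbook pathway:

* a CCR2-catalysed shunt from caffeoyl-CoA to caffeyl aldehyde, followed by
  COMT methylation to coniferyl aldehyde, running in parallel with the
  canonical CCoAOMT--CCR1 route; and
* in the *extended* variant, three irreversible "overflow" drains (v22--v24)
  that remove cinnamic acid (towards salicylate), p-coumaroyl-CoA (towards
  flavonoids) and 5-hydroxyconiferyl alcohol (incorporated into the polymer
  as the 5H unit).  Without these drains the mass balances of several
  down-regulated lines have no solution.

All reactions are irreversible with unit stoichiometry; shikimate and CoA
are treated as perfectly recycled cofactors, so the two HCT steps appear as
simple conversions.  Flux units are dimensionless: every distribution is
normalized to the entry flux v1 (phenylalanine -> cinnamic acid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "PathwayNetwork",
    "build_reference_network",
    "stoichiometric_matrix",
    "reactions_for_enzyme",
    "write_network_tsv",
    "read_network_tsv",
    "GENE_ENZYMES",
    "ENZYMES",
    "OVERFLOW_LOWER_BOUND",
    "OVERFLOW_REACTIONS",
    "TRANSPORT_REACTIONS",
]

GENE_ENZYMES: tuple[str, ...] = (
    "PAL", "C4H", "4CL", "HCT", "C3H", "CCR1", "CCR2", "CCoAOMT",
    "COMT", "F5H", "CAD",
)
ENZYMES: tuple[str, ...] = GENE_ENZYMES + ("TRANSPORT", "OVERFLOW")

#: Lower bound applied to the three overflow fluxes of the extended variant,
#: keeping them from vanishing in the subsequent maximization.
OVERFLOW_LOWER_BOUND: float = 0.01
DEFAULT_UPPER_BOUND: float = 1.0

OVERFLOW_REACTIONS: tuple[str, ...] = ("v22", "v23", "v24")
TRANSPORT_REACTIONS: tuple[str, ...] = ("v6", "v15", "v19")

VARIANTS: tuple[str, ...] = ("extended", "unextended")


@dataclass(frozen=True)
class Metabolite:
    """A pathway species; boundary species carry no mass-balance row."""

    id: str
    name: str
    is_boundary: bool = False


@dataclass(frozen=True)
class Reaction:
    """An irreversible unit-stoichiometry conversion, transport or overflow."""

    id: str
    enzyme: str
    substrate: str
    product: str
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r} for {self.id}")
        if self.lower_bound < 0:
            raise ValueError(f"{self.id}: lower bound must be >= 0 (irreversible)")
        if self.upper_bound < self.lower_bound:
            raise ValueError(f"{self.id}: upper bound below lower bound")


# (id, name, boundary) — boundary = external source/sink.
_METABOLITES: tuple[tuple[str, str, bool], ...] = (
    ("phe", "phenylalanine", True),
    ("cinnamate", "cinnamic acid", False),
    ("p_coumarate", "p-coumaric acid", False),
    ("p_coumaroyl_coa", "p-coumaroyl-CoA", False),
    ("p_coumaraldehyde", "p-coumaraldehyde", False),
    ("p_coumaryl_alcohol", "p-coumaryl alcohol", False),
    ("p_coumaroyl_shikimate", "p-coumaroyl shikimate", False),
    ("caffeoyl_shikimate", "caffeoyl shikimate", False),
    ("caffeoyl_coa", "caffeoyl-CoA", False),
    ("caffeyl_aldehyde", "caffeyl aldehyde", False),
    ("feruloyl_coa", "feruloyl-CoA", False),
    ("coniferyl_aldehyde", "coniferyl aldehyde", False),
    ("coniferyl_alcohol", "coniferyl alcohol", False),
    ("oh5_coniferyl_aldehyde", "5-hydroxyconiferyl aldehyde", False),
    ("sinapyl_aldehyde", "sinapyl aldehyde", False),
    ("sinapyl_alcohol", "sinapyl alcohol", False),
    ("oh5_coniferyl_alcohol", "5-hydroxyconiferyl alcohol", False),
    ("lignin_h", "H lignin (cell wall)", True),
    ("lignin_g", "G lignin (cell wall)", True),
    ("lignin_s", "S lignin (cell wall)", True),
    ("sink_cinnamate", "cinnamic acid overflow sink", True),
    ("sink_p_coumaroyl_coa", "p-coumaroyl-CoA overflow sink", True),
    ("sink_5h", "5H monomer sink", True),
)

# (id, enzyme, substrate, product)
_REACTIONS: tuple[tuple[str, str, str, str], ...] = (
    ("v1", "PAL", "phe", "cinnamate"),
    ("v2", "C4H", "cinnamate", "p_coumarate"),
    ("v3", "4CL", "p_coumarate", "p_coumaroyl_coa"),
    ("v4", "CCR1", "p_coumaroyl_coa", "p_coumaraldehyde"),
    ("v5", "CAD", "p_coumaraldehyde", "p_coumaryl_alcohol"),
    ("v6", "TRANSPORT", "p_coumaryl_alcohol", "lignin_h"),
    ("v7", "HCT", "p_coumaroyl_coa", "p_coumaroyl_shikimate"),
    ("v8", "C3H", "p_coumaroyl_shikimate", "caffeoyl_shikimate"),
    ("v9", "HCT", "caffeoyl_shikimate", "caffeoyl_coa"),
    ("v10", "CCR2", "caffeoyl_coa", "caffeyl_aldehyde"),
    ("v11", "CCoAOMT", "caffeoyl_coa", "feruloyl_coa"),
    ("v12", "COMT", "caffeyl_aldehyde", "coniferyl_aldehyde"),
    ("v13", "CCR1", "feruloyl_coa", "coniferyl_aldehyde"),
    ("v14", "CAD", "coniferyl_aldehyde", "coniferyl_alcohol"),
    ("v15", "TRANSPORT", "coniferyl_alcohol", "lignin_g"),
    ("v16", "F5H", "coniferyl_aldehyde", "oh5_coniferyl_aldehyde"),
    ("v17", "COMT", "oh5_coniferyl_aldehyde", "sinapyl_aldehyde"),
    ("v18", "CAD", "sinapyl_aldehyde", "sinapyl_alcohol"),
    ("v19", "TRANSPORT", "sinapyl_alcohol", "lignin_s"),
    ("v20", "F5H", "coniferyl_alcohol", "oh5_coniferyl_alcohol"),
    ("v21", "COMT", "oh5_coniferyl_alcohol", "sinapyl_alcohol"),
    ("v22", "OVERFLOW", "cinnamate", "sink_cinnamate"),
    ("v23", "OVERFLOW", "p_coumaroyl_coa", "sink_p_coumaroyl_coa"),
    ("v24", "OVERFLOW", "oh5_coniferyl_alcohol", "sink_5h"),
)

_NAME_BY_ID = {mid: name for mid, name, _ in _METABOLITES}
_BOUNDARY_IDS = frozenset(mid for mid, _, b in _METABOLITES if b)


@dataclass(frozen=True)
class PathwayNetwork:
    """Immutable pathway variant: metabolites, reactions and flux bounds."""

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    variant: str

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def internal_metabolites(self) -> tuple[Metabolite, ...]:
        return tuple(m for m in self.metabolites if not m.is_boundary)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def metabolite_name(self, mid: str) -> str:
        for m in self.metabolites:
            if m.id == mid:
                return m.name
        raise KeyError(mid)

    def producers(self, mid: str) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions if r.product == mid)

    def consumers(self, mid: str) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions if r.substrate == mid)


def _validate(net: PathwayNetwork) -> None:
    ids = [m.id for m in net.metabolites]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate metabolite ids")
    for m in net.internal_metabolites:
        if not net.producers(m.id) or not net.consumers(m.id):
            raise ValueError(f"internal metabolite {m.id} lacks producer or consumer")


def build_reference_network(variant: str = "extended") -> PathwayNetwork:
    """Return the fixed reference topology.

    ``extended`` carries 24 reactions including the three overflow drains
    (lower bound :data:`OVERFLOW_LOWER_BOUND`); ``unextended`` is the same
    map with v22--v24 and their sinks removed (21 reactions).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rows = _REACTIONS if variant == "extended" else tuple(
        r for r in _REACTIONS if r[0] not in OVERFLOW_REACTIONS
    )
    reactions = tuple(
        Reaction(
            rid, enz, sub, prod,
            lower_bound=OVERFLOW_LOWER_BOUND if enz == "OVERFLOW" else 0.0,
        )
        for rid, enz, sub, prod in rows
    )
    used = {r.substrate for r in reactions} | {r.product for r in reactions}
    metabolites = tuple(
        Metabolite(mid, name, boundary)
        for mid, name, boundary in _METABOLITES
        if mid in used
    )
    net = PathwayNetwork(metabolites, reactions, variant)
    _validate(net)
    return net


def stoichiometric_matrix(net: PathwayNetwork) -> pd.DataFrame:
    """Stoichiometric matrix N (internal metabolites x reactions).

    Entries are in {-1, 0, +1}: each reaction consumes one substrate and
    forms one product; rows for boundary species are omitted.
    """
    internal = [m.id for m in net.internal_metabolites]
    mat = pd.DataFrame(
        np.zeros((len(internal), len(net.reactions))),
        index=internal,
        columns=list(net.reaction_ids),
    )
    for r in net.reactions:
        if r.substrate in mat.index:
            mat.loc[r.substrate, r.id] -= 1.0
        if r.product in mat.index:
            mat.loc[r.product, r.id] += 1.0
    return mat


def reactions_for_enzyme(net: PathwayNetwork, enzyme: str) -> frozenset[str]:
    """Reaction ids catalysed by ``enzyme`` (several enzymes act at
    multiple steps, e.g. CAD reduces all three hydroxycinnamyl aldehydes)."""
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {ENZYMES}")
    return frozenset(r.id for r in net.reactions if r.enzyme == enzyme)


def write_network_tsv(net: PathwayNetwork, path) -> None:
    df = pd.DataFrame(
        [
            {
                "reaction_id": r.id,
                "enzyme": r.enzyme,
                "substrate": r.substrate,
                "product": r.product,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in net.reactions
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_network_tsv(path) -> PathwayNetwork:
    """Rebuild a network from the TSV written by :func:`write_network_tsv`.

    Boundary status is reconstructed structurally: a species is boundary iff
    it lacks a producing or a consuming reaction.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "enzyme", "substrate", "product",
                "lower_bound", "upper_bound"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"network TSV missing columns: {sorted(missing)}")
    reactions = tuple(
        Reaction(row.reaction_id, row.enzyme, row.substrate, row.product,
                 float(row.lower_bound), float(row.upper_bound))
        for row in df.itertuples()
    )
    produced = {r.product for r in reactions}
    consumed = {r.substrate for r in reactions}
    mids = sorted(produced | consumed,
                  key=lambda m: [x[0] for x in _METABOLITES].index(m)
                  if m in _NAME_BY_ID else 99)
    metabolites = tuple(
        Metabolite(mid, _NAME_BY_ID.get(mid, mid),
                   mid not in produced or mid not in consumed)
        for mid in mids
    )
    variant = "extended" if any(r.enzyme == "OVERFLOW" for r in reactions) else "unextended"
    net = PathwayNetwork(metabolites, reactions, variant)
    _validate(net)
    return net
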