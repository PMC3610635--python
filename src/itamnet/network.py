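"""Rule-based expansion of a chain construct into its full reaction network.

A chain species is identified by (i) the phosphorylation state of its
2n sites (a bitmask, sites indexed in phosphorylation order with the
membrane-distal ITAM first), (ii) which ITAMs carry a bound ZAP-70
(bitmask over ITAMs), and (iii) at most one bound enzyme molecule
together with the site it engages.  The rule set:

* kinase: binds an eligible unphosphorylated site (sequential: only the
  frontier site, i.e. the next site in order; random: any), and in one
  catalytic step phosphorylates it and releases;
* phosphatase: binds an eligible phosphorylated site (sequential: only
  the frontier phosphate, so dephosphorylation is last-on-first-off;
  random: any) provided ZAP-70 does not occupy that ITAM, and in one
  catalytic step removes the phosphate and releases;
* kinase and phosphatase are mutually exclusive on a chain (one enzyme
  molecule bound at a time);
* ZAP-70 binds any doubly phosphorylated ITAM not already carrying a
  ZAP-70 and with no phosphatase engaged on either of its sites, one
  ZAP-70 per ITAM, independently of events on other ITAMs; while bound
  it protects the ITAM from dephosphorylation.

Every species reachable from the unphosphorylated, unbound state under
these rules is enumerated by breadth-first closure, and every rule
application becomes one mass-action reaction.  For the wild-type
three-ITAM chain under sequential phosphorylation with ZAP-70 this
yields 53 species and 168 reactions; the random scheme expands the
same chain to several hundred species.
"""

from __future__ import annotations

import re
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Optional
from xml.etree import ElementTree as ET

from .constructs import ChainSpec, RateSet, ValidationError, SITES_PER_ITAM

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "generate_network",
    "enumerate_species",
    "network_summary",
    "export_network",
    "export_netlist",
    "import_netlist",
    "export_sbml",
]

KINASE = "kinase"
PHOSPHATASE = "phosphatase"
ZAP = "zap"
CHAIN = "chain"

RULE_TAGS = (
    "kinase_bind",
    "kinase_unbind",
    "kinase_cat",
    "phosphatase_bind",
    "phosphatase_unbind",
    "phosphatase_cat",
    "zap_bind",
    "zap_unbind",
)


@dataclass(frozen=True)
class Species:
    """One molecular species: a free molecule or a chain state.

    ``sites`` is a bitmask over the 2n phosphorylation sites (bit i set =
    site i phosphorylated), ``zap`` a bitmask over ITAMs carrying a bound
    ZAP-70, ``enzyme`` either ``None`` or ``(kind, site_index)`` for the
    single bound enzyme.
    """

    kind: str  # chain | kinase | phosphatase | zap
    sites: int = 0
    zap: int = 0
    enzyme: Optional[tuple[str, int]] = None

    def sort_key(self):
        return (self.kind, self.sites, self.zap, self.enzyme or ("", -1))

    def n_phosphates(self) -> int:
        return bin(self.sites).count("1") if self.kind == CHAIN else 0

    def n_zap_bound(self) -> int:
        return bin(self.zap).count("1") if self.kind == CHAIN else 0

    def name(self, n_sites: int = 0) -> str:
        if self.kind != CHAIN:
            return self.kind
        pat = "".join("p" if self.sites >> i & 1 else "u" for i in range(n_sites))
        parts = [pat or "-"]
        if self.zap:
            parts.append("Z" + ",".join(str(j) for j in _bits(self.zap)))
        if self.enzyme is not None:
            kind, site = self.enzyme
            parts.append(("K@" if kind == KINASE else "P@") + str(site))
        return "chain(" + ";".join(parts) + ")"


_CHAIN_NAME_RE = re.compile(
    r"^chain\(([up]*|-)(?:;Z([\d,]+))?(?:;([KP])@(\d+))?\)$"
)


def species_from_name(name: str) -> Species:
    """Parse the canonical species name back into a :class:`Species`."""
    if name in (KINASE, PHOSPHATASE, ZAP):
        return Species(kind=name)
    m = _CHAIN_NAME_RE.match(name)
    if m is None:
        raise ValidationError(f"unparseable species name {name!r}")
    pat, zaps, ekind, esite = m.groups()
    sites = 0
    if pat != "-":
        for i, ch in enumerate(pat):
            if ch == "p":
                sites |= 1 << i
    zap = 0
    if zaps:
        for j in zaps.split(","):
            zap |= 1 << int(j)
    enzyme = None
    if ekind:
        enzyme = (KINASE if ekind == "K" else PHOSPHATASE, int(esite))
    return Species(kind=CHAIN, sites=sites, zap=zap, enzyme=enzyme)


def _bits(mask: int) -> list[int]:
    return [i for i in range(mask.bit_length()) if mask >> i & 1]


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction (molecularity at most 2).

    Catalysis steps are unimolecular: the enzyme–substrate complex
    converts directly to free enzyme plus product chain.
    """

    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate_constant: float
    rule_tag: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reactants", tuple(sorted(self.reactants, key=Species.sort_key))
        )
        object.__setattr__(
            self, "products", tuple(sorted(self.products, key=Species.sort_key))
        )
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise ValidationError("molecularity must be <= 2")
        if self.rule_tag not in RULE_TAGS:
            raise ValidationError(f"unknown rule_tag {self.rule_tag!r}")


@dataclass
class ReactionNetwork:
    """The enumerated species set and mass-action reaction list of a chain."""

    spec: ChainSpec
    species: list[Species]
    reactions: list[Reaction]
    index: dict[Species, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {s: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise ValidationError("duplicate species in network")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_names(self) -> list[str]:
        n = self.spec.n_sites
        return [s.name(n) for s in self.species]

    def observable_weights(self, which: str):
        """Integer weight per species for an observable.

        ``bound_zap``: number of ZAP-70 molecules docked on the species.
        ``total_phosphorylation``: number of phosphate groups carried,
        counted on every chain isoform regardless of bound enzymes/ZAP.
        """
        if which == "bound_zap":
            return [s.n_zap_bound() for s in self.species]
        if which == "total_phosphorylation":
            return [s.n_phosphates() for s in self.species]
        raise ValidationError(f"unknown observable {which!r}")

    def composition(self):
        """Per-species counts of (chain, kinase, phosphatase, zap) molecules."""
        rows = []
        for s in self.species:
            if s.kind == CHAIN:
                enz = s.enzyme[0] if s.enzyme else None
                rows.append(
                    (
                        1,
                        1 if enz == KINASE else 0,
                        1 if enz == PHOSPHATASE else 0,
                        s.n_zap_bound(),
                    )
                )
            else:
                rows.append(
                    (
                        0,
                        1 if s.kind == KINASE else 0,
                        1 if s.kind == PHOSPHATASE else 0,
                        1 if s.kind == ZAP else 0,
                    )
                )
        return rows


# ---------------------------------------------------------------------------
# rule application


def _itam_of(site: int) -> int:
    return site // SITES_PER_ITAM

def _itam_mask(itam: int) -> int:
    return ((1 << SITES_PER_ITAM) - 1) << (SITES_PER_ITAM * itam)

def _is_full(sites: int, itam: int) -> bool:
    m = _itam_mask(itam)
    return sites & m == m

def _seq_level(sites: int) -> int:
    # sequential states keep a contiguous prefix of phosphorylated sites
    return sites.bit_length()


def _kinase_sites(spec: ChainSpec, s: Species) -> list[int]:
    n = spec.n_sites
    if spec.scheme == "sequential":
        p = _seq_level(s.sites)
        return [p] if p < n else []
    return [i for i in range(n) if not s.sites >> i & 1]


def _phosphatase_sites(spec: ChainSpec, s: Species) -> list[int]:
    if spec.scheme == "sequential":
        p = _seq_level(s.sites)
        if p >= 1 and not s.zap >> _itam_of(p - 1) & 1:
            return [p - 1]
        return []
    return [
        i for i in range(spec.n_sites)
        if s.sites >> i & 1 and not s.zap >> _itam_of(i) & 1
    ]


def _zap_itams(spec: ChainSpec, s: Species) -> list[int]:
    if not spec.zap_enabled:
        return []
    blocked = -1
    if s.enzyme is not None and s.enzyme[0] == PHOSPHATASE:
        blocked = _itam_of(s.enzyme[1])
    return [
        j for j in range(spec.n_itams)
        if _is_full(s.sites, j) and not s.zap >> j & 1 and j != blocked
    ]


def _enzyme_koff(spec: ChainSpec, rates: RateSet, kind: str, site: int) -> float:
    it = spec.itams[_itam_of(site)]
    if kind == KINASE:
        return it.kinase_koff if it.kinase_koff is not None else rates.kinase_koff
    return it.phosphatase_koff if it.phosphatase_koff is not None else rates.phosphatase_koff


def _reactions_from(spec: ChainSpec, rates: RateSet, s: Species) -> list[Reaction]:
    """All reactions with chain species ``s`` among the reactants."""
    free_k = Species(KINASE)
    free_p = Species(PHOSPHATASE)
    free_z = Species(ZAP)
    out: list[Reaction] = []

    if s.enzyme is None:
        for site in _kinase_sites(spec, s):
            bound = Species(CHAIN, s.sites, s.zap, (KINASE, site))
            out.append(Reaction((s, free_k), (bound,), rates.kinase_kon, "kinase_bind"))
        for site in _phosphatase_sites(spec, s):
            bound = Species(CHAIN, s.sites, s.zap, (PHOSPHATASE, site))
            out.append(
                Reaction((s, free_p), (bound,), rates.phosphatase_kon, "phosphatase_bind")
            )
    else:
        kind, site = s.enzyme
        released = Species(CHAIN, s.sites, s.zap, None)
        free_e = free_k if kind == KINASE else free_p
        koff = _enzyme_koff(spec, rates, kind, site)
        tag = "kinase" if kind == KINASE else "phosphatase"
        out.append(Reaction((s,), (released, free_e), koff, f"{tag}_unbind"))
        if kind == KINASE:
            product = Species(CHAIN, s.sites | 1 << site, s.zap, None)
            out.append(Reaction((s,), (product, free_e), rates.kinase_kcat, "kinase_cat"))
        else:
            product = Species(CHAIN, s.sites & ~(1 << site), s.zap, None)
            out.append(
                Reaction((s,), (product, free_e), rates.phosphatase_kcat, "phosphatase_cat")
            )

    for j in _zap_itams(spec, s):
        bound = Species(CHAIN, s.sites, s.zap | 1 << j, s.enzyme)
        out.append(Reaction((s, free_z), (bound,), spec.itams[j].zap_kon, "zap_bind"))
    for j in _bits(s.zap):
        released = Species(CHAIN, s.sites, s.zap & ~(1 << j), s.enzyme)
        out.append(Reaction((s,), (released, free_z), spec.itams[j].zap_koff, "zap_unbind"))
    return out


def generate_network(spec: ChainSpec, rates: RateSet | None = None) -> ReactionNetwork:
    """Expand a :class:`ChainSpec` into its complete reaction network.

    Breadth-first closure from the all-unphosphorylated, unbound chain:
    every rule application on a reached species adds one reaction and
    (possibly) new product species.  The three free molecules (kinase,
    phosphatase, ZAP-70) are always part of the species set.
    """
    rates = rates or RateSet()
    start = Species(CHAIN)
    seen: dict[Species, None] = {}
    reactions: dict[Reaction, None] = {}  # insertion-ordered, duplicate-free
    queue: deque[Species] = deque([start])
    seen[start] = None
    while queue:
        s = queue.popleft()
        for rxn in _reactions_from(spec, rates, s):
            reactions[rxn] = None
            for prod in rxn.products:
                if prod.kind == CHAIN and prod not in seen:
                    seen[prod] = None
                    queue.append(prod)

    species = sorted(seen, key=Species.sort_key) + [
        Species(KINASE),
        Species(PHOSPHATASE),
        Species(ZAP),
    ]
    return ReactionNetwork(spec=spec, species=species, reactions=list(reactions))


def enumerate_species(spec: ChainSpec, rates: RateSet | None = None) -> list[Species]:
    """The exhaustive duplicate-free species list reachable under the rules."""
    return generate_network(spec, rates).species


def network_summary(net: ReactionNetwork) -> dict:
    """Species count, reaction count and per-rule reaction counts."""
    tags = Counter(r.rule_tag for r in net.reactions)
    return {
        "species": net.n_species,
        "reactions": net.n_reactions,
        "by_rule": {tag: tags.get(tag, 0) for tag in RULE_TAGS},
    }


# ---------------------------------------------------------------------------
# exporters

NETLIST_HEADER = "# itamnet netlist v1"


def export_netlist(net: ReactionNetwork, path) -> None:
    """Write a human-readable netlist (tab-separated; re-importable).

    One species per ``S`` line and one reaction per ``R`` line:
    ``R<TAB>reactant + reactant<TAB>products<TAB>rate<TAB>tag``.
    """
    n = net.spec.n_sites
    lines = [
        NETLIST_HEADER,
        f"# n_itams={net.spec.n_itams}\tscheme={net.spec.scheme}\tzap_enabled={net.spec.zap_enabled}",
    ]
    for s in net.species:
        lines.append(f"S\t{s.name(n)}")
    for r in net.reactions:
        lhs = " + ".join(s.name(n) for s in r.reactants)
        rhs = " + ".join(s.name(n) for s in r.products)
        lines.append(f"R\t{lhs}\t{rhs}\t{r.rate_constant!r}\t{r.rule_tag}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def import_netlist(path, spec: ChainSpec) -> ReactionNetwork:
    """Re-read a netlist written by :func:`export_netlist`.

    The chain spec must be supplied (the netlist stores the network, not
    the kinetic provenance of each rate).
    """
    species: list[Species] = []
    reactions: list[Reaction] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                species.append(species_from_name(fields[1]))
            elif fields[0] == "R":
                _, lhs, rhs, rate, tag = fields
                reactants = tuple(species_from_name(t) for t in lhs.split(" + "))
                products = tuple(species_from_name(t) for t in rhs.split(" + "))
                reactions.append(Reaction(reactants, products, float(rate), tag))
            else:
                raise ValidationError(f"unrecognised netlist line: {line!r}")
    return ReactionNetwork(spec=spec, species=species, reactions=reactions)


def _sbml_species_id(i: int) -> str:
    return f"s{i}"


def export_sbml(net: ReactionNetwork, path) -> None:
    """Write an SBML Level 3 Version 2 document with mass-action kinetic laws.

    Uses a single well-mixed compartment; each reaction gets a local
    rate-constant parameter and a MathML product-of-reactants kinetic law.
    """
    ns = "http://www.sbml.org/sbml/level3/version2/core"
    mathml = "http://www.w3.org/1998/Math/MathML"
    ET.register_namespace("", ns)
    sbml = ET.Element(f"{{{ns}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{ns}}}model", {"id": "itamnet_model"})
    comps = ET.SubElement(model, f"{{{ns}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{ns}}}compartment",
        {"id": "cell", "spatialDimensions": "3", "size": "1", "constant": "true"},
    )
    n = net.spec.n_sites
    losp = ET.SubElement(model, f"{{{ns}}}listOfSpecies")
    for i, s in enumerate(net.species):
        ET.SubElement(
            losp,
            f"{{{ns}}}species",
            {
                "id": _sbml_species_id(i),
                "name": s.name(n),
                "compartment": "cell",
                "initialConcentration": "0",
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    lorx = ET.SubElement(model, f"{{{ns}}}listOfReactions")
    for j, r in enumerate(net.reactions):
        rx = ET.SubElement(
            lorx, f"{{{ns}}}reaction", {"id": f"r{j}", "name": r.rule_tag, "reversible": "false"}
        )
        lre = ET.SubElement(rx, f"{{{ns}}}listOfReactants")
        for sp in r.reactants:
            ET.SubElement(
                lre,
                f"{{{ns}}}speciesReference",
                {"species": _sbml_species_id(net.index[sp]), "stoichiometry": "1", "constant": "true"},
            )
        lpr = ET.SubElement(rx, f"{{{ns}}}listOfProducts")
        for sp in r.products:
            ET.SubElement(
                lpr,
                f"{{{ns}}}speciesReference",
                {"species": _sbml_species_id(net.index[sp]), "stoichiometry": "1", "constant": "true"},
            )
        kl = ET.SubElement(rx, f"{{{ns}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{mathml}}}math")
        apply_ = ET.SubElement(math, f"{{{mathml}}}apply")
        ET.SubElement(apply_, f"{{{mathml}}}times")
        ci_k = ET.SubElement(apply_, f"{{{mathml}}}ci")
        ci_k.text = f"k{j}"
        for sp in r.reactants:
            ci = ET.SubElement(apply_, f"{{{mathml}}}ci")
            ci.text = _sbml_species_id(net.index[sp])
        lop = ET.SubElement(kl, f"{{{ns}}}listOfLocalParameters")
        ET.SubElement(
            lop, f"{{{ns}}}localParameter", {"id": f"k{j}", "value": repr(r.rate_constant)}
        )
    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def export_network(net: ReactionNetwork, path, format: str = "netlist") -> None:
    """Write the network as ``sbml`` or ``netlist``."""
    if format == "sbml":
        export_sbml(net, path)
    elif format == "netlist":
        export_netlist(net, path)
    else:
        raise ValidationError(f"unknown format {format!r}; use 'sbml' or 'netlist'")
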