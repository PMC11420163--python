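"""Metabolic network model: compounds, reactions, pathways, and lookup indexes.

The network is the canvas the omics painter draws on.  It can be read from
SBML (Level 3 core, with optional ``groups`` for pathway membership and
``fbc`` for gene associations) or from a tab-delimited flat format that the
fixture generator also writes, so every network used in tests round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

COMPOUND_CLASSES = frozenset(
    {"amino_acid", "carbohydrate", "nucleotide", "lipid", "cofactor", "other"}
)

PATHWAY_TOP_CATEGORIES = frozenset({"biosynthesis", "degradation", "energy", "other"})

DATA_TYPES = frozenset({"gene", "protein", "reaction", "compound"})


class NetworkValidationError(ValueError):
    """A structural problem in network data (dangling ref, duplicate id...)."""


class FlatParseError(ValueError):
    """Malformed flat-network file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class SBMLParseError(ValueError):
    """Unreadable or invalid SBML document."""


@dataclass
class CompoundNode:
    id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    compound_class: str = "other"
    phosphorylated: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("compound id must be nonempty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise NetworkValidationError(
                f"unknown compound class {self.compound_class!r} for {self.id!r}"
            )
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    id: str
    substrate_ids: list[str] = field(default_factory=list)
    product_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    enzyme_names: list[str] = field(default_factory=list)
    pathway_ids: list[str] = field(default_factory=list)
    reversible: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("reaction id must be nonempty")
        if not self.substrate_ids and not self.product_ids:
            raise NetworkValidationError(
                f"reaction {self.id!r} has no substrates and no products"
            )


@dataclass
class Pathway:
    id: str
    name: str
    category_path: list[str]
    reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("pathway id must be nonempty")
        if not self.category_path:
            raise NetworkValidationError(f"pathway {self.id!r} has empty category path")
        if self.category_path[0] not in PATHWAY_TOP_CATEGORIES:
            raise NetworkValidationError(
                f"pathway {self.id!r}: top category {self.category_path[0]!r} "
                f"not one of {sorted(PATHWAY_TOP_CATEGORIES)}"
            )
        if not self.name:
            self.name = self.id


class MetabolicNetwork:
    """Keyed collections of compounds/reactions/pathways plus derived indexes.

    ``gene_index`` maps a case-folded gene id to the set of reaction ids it
    catalyzes; ``compound_index`` maps case-folded compound ids, names and
    synonyms to the primary compound id.  Indexes are rebuilt from the stored
    records by :meth:`reindex` and are always exactly their closure.
    """

    def __init__(
        self,
        compounds: list[CompoundNode] | None = None,
        reactions: list[Reaction] | None = None,
        pathways: list[Pathway] | None = None,
    ):
        self.compounds: dict[str, CompoundNode] = {}
        self.reactions: dict[str, Reaction] = {}
        self.pathways: dict[str, Pathway] = {}
        for c in compounds or []:
            self.add_compound(c)
        for r in reactions or []:
            self.add_reaction(r)
        for p in pathways or []:
            self.add_pathway(p)
        self.reindex()

    # -- construction -----------------------------------------------------

    def add_compound(self, c: CompoundNode) -> None:
        if c.id in self.compounds:
            raise NetworkValidationError(f"duplicate compound id {c.id!r}")
        self.compounds[c.id] = c

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self.reactions:
            raise NetworkValidationError(f"duplicate reaction id {r.id!r}")
        self.reactions[r.id] = r

    def add_pathway(self, p: Pathway) -> None:
        if p.id in self.pathways:
            raise NetworkValidationError(f"duplicate pathway id {p.id!r}")
        self.pathways[p.id] = p

    def reindex(self) -> None:
        self.gene_index: dict[str, set[str]] = {}
        self.compound_index: dict[str, str] = {}
        self._reaction_index: dict[str, str] = {}
        self._enzyme_index: dict[str, str] = {}
        for r in self.reactions.values():
            self._reaction_index.setdefault(r.id.casefold(), r.id)
            for e in r.enzyme_names:
                self._enzyme_index.setdefault(e.casefold(), r.id)
        for c in self.compounds.values():
            for token in [c.id, c.name, *c.synonyms]:
                self.compound_index.setdefault(token.casefold(), c.id)
        for r in self.reactions.values():
            for g in r.gene_ids:
                self.gene_index.setdefault(g.casefold(), set()).add(r.id)
        # pathway membership is stored on both sides; reconcile onto reactions
        for r in self.reactions.values():
            r.pathway_ids = []
        for p in self.pathways.values():
            for rid in p.reaction_ids:
                if rid in self.reactions and p.id not in self.reactions[rid].pathway_ids:
                    self.reactions[rid].pathway_ids.append(p.id)

    def validate(self) -> None:
        """Check referential integrity; raise NetworkValidationError on failure."""
        for r in self.reactions.values():
            for cid in [*r.substrate_ids, *r.product_ids]:
                if cid not in self.compounds:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown compound {cid!r}"
                    )
        for p in self.pathways.values():
            for rid in p.reaction_ids:
                if rid not in self.reactions:
                    raise NetworkValidationError(
                        f"pathway {p.id!r} references unknown reaction {rid!r}"
                    )

    # -- queries ----------------------------------------------------------

    def orphan_reactions(self) -> list[Reaction]:
        """Reactions assigned to no pathway, in stored order."""
        return [r for r in self.reactions.values() if not r.pathway_ids]

    def lookup_entity(self, token: str, data_type: str) -> set[str]:
        """Resolve an omics row token to target ids.

        gene/protein tokens resolve to the set of reactions catalyzed by that
        gene's products; reaction tokens to the reaction itself; compound
        tokens to the compound id.  Matching is case-insensitive, primary ids
        first, then names/synonyms.  Unmatched tokens yield an empty set.
        """
        if data_type not in DATA_TYPES:
            raise ValueError(f"unknown data type {data_type!r}")
        key = token.casefold()
        if data_type in ("gene", "protein"):
            hits = self.gene_index.get(key, set())
            if hits:
                return set(hits)
        elif data_type == "reaction":
            rid = self._reaction_index.get(key) or self._enzyme_index.get(key)
            if rid is not None:
                return {rid}
        else:  # compound
            cid = self.compound_index.get(key)
            if cid is not None:
                return {cid}
        log.warning("unmatched %s token %r", data_type, token)
        return set()


def lookup_entity(network: MetabolicNetwork, token: str, data_type: str) -> set[str]:
    return network.lookup_entity(token, data_type)


# -- flat format -----------------------------------------------------------
#
#   COMPOUND <tab> id <tab> name <tab> class <tab> phospho(0/1) <tab> syn1|syn2
#   REACTION <tab> id <tab> sub1,sub2 <tab> prod1 <tab> gene1,gene2 <tab> rev(0/1)
#   PATHWAY  <tab> id <tab> name <tab> category/sub <tab> r1,r2,...
#
# UTF-8, '#' comment lines allowed anywhere.


def _split_list(cell: str, sep: str) -> list[str]:
    return [t for t in (s.strip() for s in cell.split(sep)) if t]


def read_flat_network(path) -> MetabolicNetwork:
    net = MetabolicNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            kind = cells[0]
            try:
                if kind == "COMPOUND":
                    _, cid, name, cls, phospho, syn = (cells + [""] * 6)[:6]
                    net.add_compound(
                        CompoundNode(
                            id=cid,
                            name=name,
                            compound_class=cls or "other",
                            phosphorylated=phospho == "1",
                            synonyms=_split_list(syn, "|"),
                        )
                    )
                elif kind == "REACTION":
                    _, rid, subs, prods, genes, rev = (cells + [""] * 6)[:6]
                    net.add_reaction(
                        Reaction(
                            id=rid,
                            substrate_ids=_split_list(subs, ","),
                            product_ids=_split_list(prods, ","),
                            gene_ids=_split_list(genes, ","),
                            reversible=rev == "1",
                        )
                    )
                elif kind == "PATHWAY":
                    _, pid, name, cat, rids = (cells + [""] * 5)[:5]
                    net.add_pathway(
                        Pathway(
                            id=pid,
                            name=name,
                            category_path=_split_list(cat, "/"),
                            reaction_ids=_split_list(rids, ","),
                        )
                    )
                else:
                    raise FlatParseError(f"unknown record type {kind!r}", lineno)
            except NetworkValidationError as exc:
                raise FlatParseError(str(exc), lineno) from exc
    net.reindex()
    net.validate()
    return net


def write_flat_network(net: MetabolicNetwork, path, manifest: bool = True) -> None:
    """Serialize to the flat format; prefixed with a manifest comment of counts."""
    lines: list[str] = []
    if manifest:
        lines.append(
            f"# manifest: compounds={len(net.compounds)} "
            f"reactions={len(net.reactions)} pathways={len(net.pathways)}"
        )
    for c in net.compounds.values():
        lines.append(
            "\t".join(
                [
                    "COMPOUND",
                    c.id,
                    c.name,
                    c.compound_class,
                    "1" if c.phosphorylated else "0",
                    "|".join(c.synonyms),
                ]
            )
        )
    for r in net.reactions.values():
        lines.append(
            "\t".join(
                [
                    "REACTION",
                    r.id,
                    ",".join(r.substrate_ids),
                    ",".join(r.product_ids),
                    ",".join(r.gene_ids),
                    "1" if r.reversible else "0",
                ]
            )
        )
    for p in net.pathways.values():
        lines.append(
            "\t".join(
                [
                    "PATHWAY",
                    p.id,
                    p.name,
                    "/".join(p.category_path),
                    ",".join(p.reaction_ids),
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_flat_manifest(path) -> dict[str, int]:
    """Parse the generator's ``# manifest:`` comment, if present."""
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("# manifest:"):
                pairs = line.removeprefix("# manifest:").split()
                return {k: int(v) for k, v in (p.split("=") for p in pairs)}
    return {}


# -- SBML ------------------------------------------------------------------


def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML L2/L3 model.

    Species become compounds (boundary species included, so currency
    metabolites remain paintable); reactions keep fbc gene-product
    associations as gene ids; SBML ``groups`` whose members are reactions
    become pathways (category "other" — SBML carries no pathway taxonomy).
    Reactions in no group are orphans.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(
                f"SBML error at line {err.getLine()}: {err.getMessage().strip()}"
            )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError(f"no model element in {path}")

    net = MetabolicNetwork()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        net.add_compound(CompoundNode(id=sp.getId(), name=sp.getName() or sp.getId()))

    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        subs = [rx.getReactant(j).getSpecies() for j in range(rx.getNumReactants())]
        prods = [rx.getProduct(j).getSpecies() for j in range(rx.getNumProducts())]
        genes = _fbc_gene_ids(rx)
        net.add_reaction(
            Reaction(
                id=rx.getId(),
                substrate_ids=subs,
                product_ids=prods,
                gene_ids=genes,
                enzyme_names=[rx.getName()] if rx.getName() else [],
                reversible=bool(rx.getReversible()),
            )
        )

    gplug = model.getPlugin("groups")
    if gplug is not None:
        for i in range(gplug.getNumGroups()):
            grp = gplug.getGroup(i)
            rids = []
            for j in range(grp.getNumMembers()):
                ref = grp.getMember(j).getIdRef()
                if ref in net.reactions:
                    rids.append(ref)
            net.add_pathway(
                Pathway(
                    id=grp.getId() or f"group_{i}",
                    name=grp.getName() or grp.getId(),
                    category_path=["other"],
                    reaction_ids=rids,
                )
            )

    net.reindex()
    net.validate()
    return net


def _fbc_gene_ids(rx) -> list[str]:
    plug = rx.getPlugin("fbc")
    if plug is None:
        return []
    gpa = plug.getGeneProductAssociation()
    if gpa is None:
        return []
    genes: list[str] = []

    def walk(assoc):
        if assoc is None:
            return
        if hasattr(assoc, "getGeneProduct") and assoc.getGeneProduct():
            gid = assoc.getGeneProduct()
            if gid not in genes:
                genes.append(gid)
        if hasattr(assoc, "getNumAssociations"):
            for k in range(assoc.getNumAssociations()):
                walk(assoc.getAssociation(k))

    walk(gpa.getAssociation())
    return genes
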