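"""Deterministic fixture generators: toy networks and omics experiments.

These generators stand in for real pathway-database downloads.  They emit
networks in the flat format and experiments in the single-file format, shaped
like the two case studies the painter targets:

* ``abaylyi-like`` — three one-column datasets (a log2 expression contrast on
  edge color, knockout growth yields on edge thickness, metabolite scores on
  node color): a single-condition carbon-source-shift experiment.
* ``synechocystis-like`` — transcriptomics and proteomics across five time
  points (1 h, 3 h, 11.75 h, 13 h, 15 h spanning a light-to-dark transition)
  plus a single-column metabolomics score list.  Fold-change preprocessing
  against the 1 h time point turns the five raw columns into four.

Everything is seeded; a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .network import CompoundNode, MetabolicNetwork, Pathway, Reaction, write_flat_network
from .omics import (
    DatasetSpec,
    MultiOmicsExperiment,
    OmicsTable,
    SingleOmicsDataset,
    write_single_file,
)

COMPOUND_CLASS_CYCLE = ["other", "carbohydrate", "amino_acid", "nucleotide", "cofactor", "lipid"]

SYNECHOCYSTIS_TIMEPOINTS = ["1 h", "3 h", "11.75 h", "13 h", "15 h"]


@dataclass
class DatasetFixtureSpec:
    dataset_id: str
    label: str
    data_type: str
    target_channel: str
    n_columns: int = 1
    distribution: tuple = ("normal", 0.0, 2.0)  # ("normal",mu,sigma)|("lognormal",mu,sigma)|("uniform",a,b)
    fraction_missing: float = 0.0
    fraction_unmatched_tokens: float = 0.0
    signed: bool = True
    n_rows: int | None = None  # default: every available token
    column_labels: list[str] | None = None

    def __post_init__(self):
        if not 0 <= self.fraction_missing <= 1:
            raise ValueError("fraction_missing must be in [0, 1]")
        if not 0 <= self.fraction_unmatched_tokens <= 1:
            raise ValueError("fraction_unmatched_tokens must be in [0, 1]")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")


@dataclass
class FixtureSpec:
    n_pathways: int = 2
    reactions_per_pathway: int = 4
    n_orphan_reactions: int = 3
    datasets: list[DatasetFixtureSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pathways, self.reactions_per_pathway, self.n_orphan_reactions) < 0:
            raise ValueError("counts must be nonnegative")
        if len(self.datasets) > 4:
            raise ValueError("at most 4 datasets per experiment")


# -- network generation ----------------------------------------------------


def generate_toy_network(spec: FixtureSpec, out_path=None) -> MetabolicNetwork:
    """Generate a deterministic toy network.

    Pathways alternate between biosynthesis and degradation categories; each
    is a linear chain of fresh compounds; orphan reactions connect fresh
    compound pairs; every reaction carries 1-3 genes.
    """
    rng = random.Random(spec.seed)
    net = MetabolicNetwork()
    c_i = 0
    g_i = 0

    def new_compound() -> str:
        nonlocal c_i
        c_i += 1
        cid = f"cpd{c_i:04d}"
        net.add_compound(
            CompoundNode(
                id=cid,
                name=f"compound {c_i}",
                compound_class=COMPOUND_CLASS_CYCLE[c_i % len(COMPOUND_CLASS_CYCLE)],
                phosphorylated=(c_i % 7 == 0),
                synonyms=[f"syn-{cid}"],
            )
        )
        return cid

    def new_genes() -> list[str]:
        nonlocal g_i
        out = []
        for _ in range(rng.randint(1, 3)):
            g_i += 1
            out.append(f"g{g_i:04d}")
        return out

    r_i = 0
    for p in range(spec.n_pathways):
        cat = (
            ["biosynthesis", "toy"] if p % 2 == 0 else ["degradation", "toy"]
        )
        chain = [new_compound() for _ in range(spec.reactions_per_pathway + 1)]
        rids = []
        for k in range(spec.reactions_per_pathway):
            r_i += 1
            rid = f"rxn{r_i:04d}"
            net.add_reaction(
                Reaction(
                    id=rid,
                    substrate_ids=[chain[k]],
                    product_ids=[chain[k + 1]],
                    gene_ids=new_genes(),
                    reversible=rng.random() < 0.2,
                )
            )
            rids.append(rid)
        net.add_pathway(
            Pathway(
                id=f"pwy{p + 1:03d}",
                name=f"toy pathway {p + 1}",
                category_path=cat,
                reaction_ids=rids,
            )
        )
    for _ in range(spec.n_orphan_reactions):
        r_i += 1
        net.add_reaction(
            Reaction(
                id=f"rxn{r_i:04d}",
                substrate_ids=[new_compound()],
                product_ids=[new_compound()],
                gene_ids=new_genes(),
            )
        )
    net.reindex()
    net.validate()
    if out_path is not None:
        write_flat_network(net, out_path)
    return net


def toy_quinate_network(out_path=None) -> MetabolicNetwork:
    """Hand-written toy network echoing a quinate-degradation case study.

    Synthetic stand-in for a real organism's pathway database: 11 compounds,
    9 reactions (3 orphans), one degradation and one biosynthesis pathway.
    """
    compounds = [
        CompoundNode("quinate", "quinate", ["quinic acid"], "carbohydrate", False),
        CompoundNode("dhq", "3-dehydroquinate", [], "other", False),
        CompoundNode("dhs", "3-dehydroshikimate", [], "other", False),
        CompoundNode("pca", "protocatechuate", [], "other", False),
        CompoundNode("bka", "beta-ketoadipate", [], "other", False),
        CompoundNode("chorismate", "chorismate", [], "other", False),
        CompoundNode("prephenate", "prephenate", [], "other", False),
        CompoundNode("phe", "L-phenylalanine", ["phenylalanine"], "amino_acid", False),
        CompoundNode("succ", "succinate", [], "other", False),
        CompoundNode("fum", "fumarate", [], "other", False),
        CompoundNode("mal", "malate", [], "other", False),
    ]
    reactions = [
        Reaction("r-quiA", ["quinate"], ["dhq"], ["quiA"], ["quinate dehydrogenase"]),
        Reaction("r-quiB", ["dhq"], ["dhs"], ["quiB"], ["dehydroquinate dehydratase"]),
        Reaction("r-quiC", ["dhs"], ["pca"], ["quiC"], ["dehydroshikimate dehydratase"]),
        Reaction("r-pcaGH", ["pca"], ["bka"], ["pcaG", "pcaH"],
                 ["protocatechuate dioxygenase"]),
        Reaction("r-aroQ", ["chorismate"], ["prephenate"], ["aroQ"], ["chorismate mutase"]),
        Reaction("r-pheA", ["prephenate"], ["phe"], ["pheA"], ["prephenate dehydratase"]),
        Reaction("r-sdh", ["succ"], ["fum"], ["sdhA"], ["succinate dehydrogenase"]),
        Reaction("r-fum", ["fum"], ["mal"], ["fumC"], ["fumarase"]),
        Reaction("r-mqo", ["mal"], ["succ"], ["mqo"], ["malate oxidase"]),
    ]
    pathways = [
        Pathway("pwy-quinate-deg", "quinate degradation",
                ["degradation", "aromatic"], ["r-quiA", "r-quiB", "r-quiC", "r-pcaGH"]),
        Pathway("pwy-aaa-biosyn", "aromatic amino acid biosynthesis",
                ["biosynthesis", "amino_acid"], ["r-aroQ", "r-pheA"]),
    ]
    net = MetabolicNetwork(compounds, reactions, pathways)
    net.validate()
    if out_path is not None:
        write_flat_network(net, out_path)
    return net


# -- experiment generation -------------------------------------------------


def _draw(rng: random.Random, dist: tuple) -> float:
    kind = dist[0]
    if kind == "normal":
        return rng.gauss(dist[1], dist[2])
    if kind == "lognormal":
        return rng.lognormvariate(dist[1], dist[2])
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2])
    raise ValueError(f"unknown distribution {kind!r}")


def _tokens_for(network: MetabolicNetwork, data_type: str) -> list[str]:
    if data_type == "compound":
        return sorted(network.compounds)
    if data_type == "reaction":
        return sorted(network.reactions)
    return sorted({g for r in network.reactions.values() for g in r.gene_ids})


def generate_experiment(
    spec: FixtureSpec, network: MetabolicNetwork, out_path=None
) -> MultiOmicsExperiment:
    """Sample an experiment against a network's genes/reactions/compounds.

    The configured fraction of rows get deliberately unmatchable tokens, and
    the configured fraction of cells are missing; both exercise the painter's
    warning paths the way real exports do.
    """
    if not spec.datasets:
        raise ValueError("spec lists no datasets")
    rng = random.Random(spec.seed)
    datasets = []
    for ds in spec.datasets:
        pool = _tokens_for(network, ds.data_type)
        n_rows = ds.n_rows if ds.n_rows is not None else len(pool)
        if n_rows <= len(pool):
            tokens = pool[:n_rows]
        else:
            tokens = pool + [
                f"extra-{ds.dataset_id}-{i}" for i in range(n_rows - len(pool))
            ]
        n_unmatched = round(ds.fraction_unmatched_tokens * len(tokens))
        for i in range(n_unmatched):
            tokens[len(tokens) - 1 - i] = f"unmatched-{ds.dataset_id}-{i}"
        rows = []
        for tok in tokens:
            values = [
                None if rng.random() < ds.fraction_missing else _draw(rng, ds.distribution)
                for _ in range(ds.n_columns)
            ]
            rows.append((tok, values))
        datasets.append(
            SingleOmicsDataset(
                spec=DatasetSpec(
                    dataset_id=ds.dataset_id,
                    label=ds.label,
                    data_type=ds.data_type,
                    target_channel=ds.target_channel,
                    signed=ds.signed,
                ),
                table=OmicsTable(
                    rows=rows, n_columns=ds.n_columns, column_labels=ds.column_labels
                ),
            )
        )
    exp = MultiOmicsExperiment(datasets=datasets)
    if out_path is not None:
        write_single_file(exp, out_path)
    return exp


# -- presets ---------------------------------------------------------------

PRESETS = ("abaylyi-like", "synechocystis-like")


def preset_fixture_spec(preset: str, seed: int = 0) -> FixtureSpec:
    """Fixture spec shaped like one of the two case-study experiments."""
    if preset == "abaylyi-like":
        return FixtureSpec(
            n_pathways=4,
            reactions_per_pathway=4,
            n_orphan_reactions=4,
            seed=seed,
            datasets=[
                DatasetFixtureSpec(
                    "tx", "expression log2 FC (succinate vs quinate)",
                    "gene", "edge_color",
                    n_columns=1, distribution=("normal", 0.0, 3.0), signed=True,
                ),
                DatasetFixtureSpec(
                    "ess", "knockout growth yield", "gene", "edge_thickness",
                    n_columns=1, distribution=("uniform", 0.0, 1.0), signed=False,
                ),
                DatasetFixtureSpec(
                    "met", "metabolite log2 abundance change", "compound", "node_color",
                    n_columns=1, distribution=("normal", 0.0, 2.0), signed=True,
                ),
            ],
        )
    if preset == "synechocystis-like":
        return FixtureSpec(
            n_pathways=4,
            reactions_per_pathway=4,
            n_orphan_reactions=4,
            seed=seed,
            datasets=[
                DatasetFixtureSpec(
                    "tx", "transcript abundance", "gene", "edge_color",
                    n_columns=5, distribution=("lognormal", 3.0, 1.0), signed=False,
                    column_labels=list(SYNECHOCYSTIS_TIMEPOINTS),
                    fraction_missing=0.02,
                ),
                DatasetFixtureSpec(
                    "prot", "protein abundance", "protein", "edge_thickness",
                    n_columns=5, distribution=("lognormal", 5.0, 1.0), signed=False,
                    column_labels=list(SYNECHOCYSTIS_TIMEPOINTS),
                    fraction_missing=0.05,
                ),
                DatasetFixtureSpec(
                    "met", "most-changed metabolite score", "compound", "node_color",
                    n_columns=1, distribution=("normal", 0.0, 2.0), signed=True,
                ),
            ],
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def generate_preset(
    preset: str, seed: int = 0, network_out=None, experiment_out=None
) -> tuple[MetabolicNetwork, MultiOmicsExperiment]:
    spec = preset_fixture_spec(preset, seed)
    net = generate_toy_network(spec, out_path=network_out)
    exp = generate_experiment(spec, net, out_path=experiment_out)
    return net, exp
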