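import random

import pytest

from metapaint import (
    CompoundNode,
    MetabolicNetwork,
    Pathway,
    Reaction,
    toy_quinate_network,
)
from metapaint.fixtures import DatasetFixtureSpec, FixtureSpec, generate_experiment
from metapaint.omics import (
    DatasetSpec,
    MultiOmicsExperiment,
    OmicsTable,
    SingleOmicsDataset,
)


@pytest.fixture(scope="session")
def quinate_net() -> MetabolicNetwork:
    return toy_quinate_network()


@pytest.fixture
def tiny_net() -> MetabolicNetwork:
    """Two-reaction network where gene g1 catalyzes both reactions."""
    compounds = [CompoundNode(c) for c in ("A", "B", "C")]
    reactions = [
        Reaction("r1", ["A"], ["B"], ["g1"]),
        Reaction("r2", ["B"], ["C"], ["g1", "g2"]),
    ]
    pathways = [Pathway("p1", "chain", ["other"], ["r1", "r2"])]
    return MetabolicNetwork(compounds, reactions, pathways)


def make_dataset(
    dataset_id="ds",
    data_type="gene",
    channel="edge_color",
    rows=(("g1", [1.0]),),
    n_columns=1,
    signed=True,
    column_selection=(),
    labels=None,
) -> SingleOmicsDataset:
    return SingleOmicsDataset(
        spec=DatasetSpec(
            dataset_id=dataset_id,
            label=dataset_id,
            data_type=data_type,
            target_channel=channel,
            column_selection=list(column_selection),
            signed=signed,
        ),
        table=OmicsTable(
            rows=[(t, list(v)) for t, v in rows],
            n_columns=n_columns,
            column_labels=labels,
        ),
    )


def random_experiment(rng: random.Random) -> MultiOmicsExperiment:
    """A random valid experiment: 1-4 datasets, ragged widths, missing cells."""
    n_ds = rng.randint(1, 4)
    channels = rng.sample(
        ["edge_color", "edge_thickness", "node_color", "node_thickness"], n_ds
    )
    datasets = []
    for i, ch in enumerate(channels):
        dtype = "compound" if ch.startswith("node") else rng.choice(
            ["gene", "protein", "reaction"]
        )
        n_cols = rng.randint(1, 5)
        n_rows = rng.randint(1, 8)
        rows = []
        for r in range(n_rows):
            values = [
                None if rng.random() < 0.15 else round(rng.uniform(-50, 50), 3)
                for _ in range(n_cols)
            ]
            rows.append((f"tok{i}_{r}", values))
        labels = None
        if rng.random() < 0.5:
            labels = [f"{h} h" for h in range(n_cols)]
        datasets.append(
            make_dataset(
                dataset_id=f"d{i}",
                data_type=dtype,
                channel=ch,
                rows=rows,
                n_columns=n_cols,
                signed=rng.random() < 0.5,
                column_selection=sorted(
                    rng.sample(range(1, n_cols + 1), rng.randint(1, n_cols))
                )
                if rng.random() < 0.4
                else (),
                labels=labels,
            )
        )
    return MultiOmicsExperiment(datasets=datasets)


@pytest.fixture
def fluxy_spec() -> FixtureSpec:
    """Medium generated network + experiment touching all four channels."""
    return FixtureSpec(
        n_pathways=6,
        reactions_per_pathway=5,
        n_orphan_reactions=8,
        seed=11,
        datasets=[
            DatasetFixtureSpec("tx", "tx", "gene", "edge_color", n_columns=3),
            DatasetFixtureSpec("fx", "fx", "reaction", "edge_thickness", n_columns=3,
                               distribution=("uniform", 0.0, 9.0), signed=False),
            DatasetFixtureSpec("mc", "mc", "compound", "node_color", n_columns=1),
            DatasetFixtureSpec("mt", "mt", "compound", "node_thickness", n_columns=2,
                               distribution=("uniform", 0.0, 4.0), signed=False),
        ],
    )


@pytest.fixture
def fluxy(fluxy_spec):
    from metapaint.fixtures import generate_toy_network

    net = generate_toy_network(fluxy_spec)
    exp = generate_experiment(fluxy_spec, net)
    return net, exp
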