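"""Shared fixtures: small synthetic configurations and toy networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexmod import syndata
from coexmod.netbuild import CoexpressionNetwork


def make_config(
    n_genes: int = 300,
    n_samples: int = 60,
    module_sizes: tuple[int, ...] = (30, 30),
    noise_sd: float = 0.4,
    seed: int = 0,
    with_tissues: bool = True,
    **kwargs,
) -> syndata.SynConfig:
    """A valid SynConfig scaled down from the default study conditions."""
    modules = tuple(syndata.ModuleSpec(size=s, noise_sd=noise_sd) for s in module_sizes)
    if with_tissues and module_sizes:
        half = n_samples // 2
        shifts_a = tuple(1.0 if m % 2 == 0 else -0.5 for m in range(len(module_sizes)))
        shifts_b = tuple(-s for s in shifts_a)
        tissues = (
            syndata.TissueSpec("tissue_a", half, shifts_a),
            syndata.TissueSpec("tissue_b", n_samples - half, shifts_b),
        )
    else:
        tissues = ()
    defaults = dict(
        n_genes=n_genes,
        n_samples=n_samples,
        modules=modules,
        tissues=tissues,
        n_redundant_groups=2,
        redundancy_size=3,
        go_terms=(
            syndata.GoTermSpec("GO:0009834", "plant-type secondary cell wall biogenesis",
                               0.02, 0, 0.8),
            syndata.GoTermSpec("GO:0006412", "translation", 0.10),
        ) if module_sizes else (),
        motif=syndata.MotifSpec("ACCCCC", 0) if module_sizes else None,
        promoter_len=500,
        seed=seed,
    )
    defaults.update(kwargs)
    return syndata.SynConfig(**defaults)


def network_from_edges(edge_list: list[tuple[str, str]]) -> CoexpressionNetwork:
    """Unit-correlation network from an explicit edge list (test helper)."""
    rows = [(min(a, b), max(a, b), 1.0) for a, b in edge_list]
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).sort_values(
        ["gene_a", "gene_b"], ignore_index=True
    )
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return CoexpressionNetwork(nodes=nodes, edges=edges, cutoff=0.5)


def clique_edges(names: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles() -> CoexpressionNetwork:
    return network_from_edges(
        clique_edges(["a1", "a2", "a3"]) + clique_edges(["b1", "b2", "b3"])
    )
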