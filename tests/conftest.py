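from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from symarch import AnnotatedGenome, GeneModel, Scaffold, ScaffoldSet


def make_genome(scaffold_seqs: dict[str, str], genes: list[GeneModel]) -> AnnotatedGenome:
    scaffolds = ScaffoldSet(Scaffold(sid, seq) for sid, seq in scaffold_seqs.items())
    return AnnotatedGenome(scaffolds=scaffolds, genes=genes)


def gene(gid, scaffold, strand, exons, **kw) -> GeneModel:
    return GeneModel(id=gid, scaffold_id=scaffold, strand=strand,
                     exons=tuple(exons), **kw)


@pytest.fixture
def two_gene_genome() -> AnnotatedGenome:
    """Two plus-strand genes at 1..100 and 201..300 on one 1 Mb scaffold."""
    seq = "A" * 1_000_000
    return make_genome(
        {"s1": seq},
        [gene("g1", "s1", "+", [(1, 100)]), gene("g2", "s1", "+", [(201, 300)])],
    )
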