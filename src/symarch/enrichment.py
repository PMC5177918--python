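"""Protein-domain enrichment: ratios, Fisher screens, BH-FDR, z-scores.

The three-tier screen compares the relative frequency of each Pfam-style
domain in one or more in-group species (the *Symbiodinium* genomes) against
the average count in a set of outgroup species. Counts are normalized to
each species' total domain count (the "domain ratio" x); p-values come from
Fisher's exact test on the in-group count against the averaged outgroup
count; BH-FDR correction runs within each in-group species' test family;
and z = (x - u) / s standardizes each domain's ratio across species for
heatmap display, with u and s the cross-species mean and (sample) standard
deviation of the ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact

from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .model import DomainHit
from .util import round_half_away


@dataclass
class DomainCountMatrix:
    """Species x domain counts with per-species totals."""

    counts: pd.DataFrame  # index: species, columns: domains, values: int

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ConfigError("domain counts must be non-negative")

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, int]]) -> "DomainCountMatrix":
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        return cls(df.sort_index(axis=1))

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def domains(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "DomainCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="species").astype(int)
        return cls(df)


@dataclass
class EnrichmentRecord:
    domain: str
    p_values: dict[str, float]  # per in-group species
    q_values: dict[str, float]
    x: dict[str, float]  # domain ratio per species (all species)
    u: float  # cross-species mean ratio
    s: float  # cross-species sample standard deviation of ratios
    z: dict[str, float]
    enriched_in: list[str] = field(default_factory=list)


@dataclass
class ScreenConfig:
    in_group: tuple[str, ...]
    out_group: tuple[str, ...]
    fdr_threshold: float = 0.001
    sidedness: str = "greater"  # "greater" (enrichment) or "two-sided"

    def __post_init__(self):
        self.in_group = tuple(self.in_group)
        self.out_group = tuple(self.out_group)
        if not self.in_group or not self.out_group:
            raise ConfigError("in-group and out-group must both be non-empty")
        if set(self.in_group) & set(self.out_group):
            raise ConfigError("in-group and out-group overlap")
        if self.sidedness not in ("greater", "two-sided", "less"):
            raise ConfigError(f"bad sidedness {self.sidedness!r}")


def count_domains(
    domain_hits: Iterable[DomainHit],
    per_protein: bool = False,
    max_i_evalue: float = 1e-5,
) -> dict[str, int]:
    """One species' domain-count row from its domain-hit list.

    Default policy counts every qualifying domain instance; ``per_protein``
    counts each (protein, domain) pair at most once. Hits with independent
    e-value above ``max_i_evalue`` are ignored.
    """
    counts: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for h in domain_hits:
        if h.i_evalue > max_i_evalue:
            continue
        if per_protein:
            key = (h.protein, h.domain_accession)
            if key in seen:
                continue
            seen.add(key)
        counts[h.domain_accession] = counts.get(h.domain_accession, 0) + 1
    return counts


def domain_ratios(matrix: DomainCountMatrix) -> pd.DataFrame:
    """Counts normalized to each species' total domain count (rows sum to 1)."""
    totals = matrix.totals
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"species with zero total domain count: {zero}")
    return matrix.counts.div(totals, axis=0)


def fisher_vs_outgroup(
    count_in: int,
    total_in: int,
    outgroup_counts: Sequence[int],
    outgroup_totals: Sequence[int],
    sidedness: str = "greater",
) -> float:
    """Fisher's exact p for one in-group count against the averaged outgroup.

    The 2x2 table is [[count_in, total_in - count_in], [k, t - k]] where k
    and t are the arithmetic means of the outgroup counts and totals, each
    rounded half away from zero to an integer (the averaging convention for
    "average counts in the outgroups").
    """
    if count_in > total_in:
        raise ValueError("count_in exceeds total_in")
    if len(outgroup_counts) != len(outgroup_totals) or not outgroup_counts:
        raise ValueError("outgroup counts/totals must be non-empty and aligned")
    k = int(round_half_away(float(np.mean(outgroup_counts))))
    t = int(round_half_away(float(np.mean(outgroup_totals))))
    if k > t:
        raise ValueError("rounded outgroup count exceeds rounded outgroup total")
    table = [[count_in, total_in - count_in], [k, t - k]]
    alternative = {"greater": "greater", "less": "less", "two-sided": "two-sided"}[
        sidedness
    ]
    _, p = fisher_exact(table, alternative=alternative)
    return float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def zscore_matrix(ratio_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-domain standardized ratios across species: z = (x - u) / s.

    u and s are the mean and sample (n-1) standard deviation of the domain's
    ratios over species; domains constant across species (s = 0) get z = 0.
    Requires at least two species.
    """
    if ratio_matrix.shape[0] < 2:
        raise ValueError("z-scores require at least two species")
    u = ratio_matrix.mean(axis=0)
    s = ratio_matrix.std(axis=0, ddof=1)
    z = (ratio_matrix - u).div(s.replace(0.0, np.nan), axis=1)
    return z.fillna(0.0)


def enrichment_screen(
    matrix: DomainCountMatrix, config: ScreenConfig
) -> tuple[set[str], list[EnrichmentRecord]]:
    """Run the Fisher/BH screen over every domain for each in-group species.

    A domain is enriched iff its BH q-value is below the configured FDR
    threshold for at least one in-group species (and, under one-sided
    screening, its ratio exceeds the mean outgroup ratio). The BH family is
    all domains within one in-group species' screen.
    """
    for sp in config.in_group + config.out_group:
        if sp not in matrix.counts.index:
            raise ConfigError(f"species {sp!r} absent from count matrix")
    counts = matrix.counts
    totals = matrix.totals
    ratios = domain_ratios(matrix)
    out_counts = counts.loc[list(config.out_group)]
    out_totals = [int(totals[sp]) for sp in config.out_group]
    domains = matrix.domains

    p_by_species: dict[str, np.ndarray] = {}
    q_by_species: dict[str, np.ndarray] = {}
    for sp in config.in_group:
        ps = np.array(
            [
                fisher_vs_outgroup(
                    int(counts.at[sp, d]),
                    int(totals[sp]),
                    out_counts[d].tolist(),
                    out_totals,
                    config.sidedness,
                )
                for d in domains
            ]
        )
        p_by_species[sp] = ps
        q_by_species[sp] = bh_fdr(ps)

    zmat = zscore_matrix(ratios)
    u = ratios.mean(axis=0)
    s = ratios.std(axis=0, ddof=1)
    mean_out_ratio = ratios.loc[list(config.out_group)].mean(axis=0)

    enriched: set[str] = set()
    records: list[EnrichmentRecord] = []
    for j, d in enumerate(domains):
        hit_species = []
        for sp in config.in_group:
            if q_by_species[sp][j] < config.fdr_threshold:
                if config.sidedness == "greater" and not (
                    ratios.at[sp, d] > mean_out_ratio[d]
                ):
                    continue
                hit_species.append(sp)
        if hit_species:
            enriched.add(d)
        records.append(
            EnrichmentRecord(
                domain=d,
                p_values={sp: float(p_by_species[sp][j]) for sp in config.in_group},
                q_values={sp: float(q_by_species[sp][j]) for sp in config.in_group},
                x={sp: float(ratios.at[sp, d]) for sp in matrix.species},
                u=float(u[d]),
                s=float(s[d]),
                z={sp: float(zmat.at[sp, d]) for sp in matrix.species},
                enriched_in=hit_species,
            )
        )
    return enriched, records


def specific_set(
    screen_a: Iterable[str], screen_b: Iterable[str]
) -> tuple[set[str], dict[str, list[str]]]:
    """Intersection of two enriched-domain sets with per-domain provenance."""
    a, b = set(screen_a), set(screen_b)
    shared = a & b
    provenance = {
        d: (["screen_a"] if d in a else []) + (["screen_b"] if d in b else [])
        for d in a | b
    }
    return shared, provenance


def cluster_order(
    z_matrix: pd.DataFrame, method: str = "complete"
) -> tuple[list, list]:
    """Row and column leaf orders from hierarchical clustering of z-scores.

    Agglomerative clustering with Euclidean distance; complete linkage by
    default (``method="average"`` available). Ties resolve deterministically
    (scipy merges lower original indices first), so permuting the input
    yields the same tree up to relabeling.
    """
    values = z_matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("z matrix contains non-finite entries")

    def order(mat: np.ndarray, labels: list) -> list:
        if mat.shape[0] < 2:
            return list(labels)
        lk = linkage(pdist(mat, metric="euclidean"), method=method)
        return [labels[i] for i in leaves_list(lk)]

    rows = order(values, list(z_matrix.index))
    cols = order(values.T, list(z_matrix.columns))
    return rows, cols


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten EnrichmentRecords into a table for TSV export."""
    rows = []
    for r in records:
        row: dict = {"domain": r.domain, "u": r.u, "s": r.s,
                     "enriched_in": ",".join(r.enriched_in)}
        for sp, v in r.x.items():
            row[f"x.{sp}"] = v
        for sp, v in r.z.items():
            row[f"z.{sp}"] = v
        for sp, v in r.p_values.items():
            row[f"p.{sp}"] = v
        for sp, v in r.q_values.items():
            row[f"q.{sp}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
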