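"""Genomic-context analysis around focal genes.

Extract a +/- flank window (default 5 kb each side) around each focal gene,
annotate every overlapping neighbor gene with domain profile HMMs, and count
domain *presence* per genome per clade: a domain counts once per genome no
matter how many neighbors, repeats, or focal-gene copies carry it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import DataIntegrityError, InvalidArgumentError, MissingIdError, MissingTaxonomyError
from .phmm import ProfileHMM, evalue, forward_bits_many

DEFAULT_FLANK_BP = 5000
DEFAULT_TOP_K = 25


@dataclass(frozen=True)
class NeighborGene:
    gene_id: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass
class GeneNeighborhood:
    focal_id: str
    genome: str
    contig: str
    window_start: int  # 0-based half-open
    window_end: int
    neighbors: list[NeighborGene]
    hits: dict[str, set[str]] = field(default_factory=dict)  # gene id -> domain names


def extract_window(gene_table: pd.DataFrame, focal_id: str, flank_bp: int = DEFAULT_FLANK_BP) -> GeneNeighborhood:
    """Neighborhood of ``focal_id``: genes overlapping the flanked window by >= 1 bp.

    ``gene_table`` uses 1-based inclusive coordinates (as written to disk);
    the window is computed 0-based half-open and clipped at the contig start
    and at the last annotated base of the contig. The focal gene itself is
    excluded from the neighbor list.
    """
    if flank_bp <= 0:
        raise InvalidArgumentError("flank_bp must be > 0")
    rows = gene_table.loc[gene_table["gene_id"] == focal_id]
    if len(rows) == 0:
        raise MissingIdError(focal_id)
    focal = rows.iloc[0]
    contig_genes = gene_table.loc[
        (gene_table["genome"] == focal["genome"]) & (gene_table["contig"] == focal["contig"])
    ]
    f_start0, f_end0 = int(focal["start"]) - 1, int(focal["end"])
    contig_end = int(contig_genes["end"].max())
    win_start = max(f_start0 - flank_bp, 0)
    win_end = min(f_end0 + flank_bp, contig_end)
    neighbors = []
    for _, g in contig_genes.iterrows():
        if g["gene_id"] == focal_id:
            continue
        g_start0, g_end0 = int(g["start"]) - 1, int(g["end"])
        if g_start0 < win_end and g_end0 > win_start:  # >= 1 bp overlap, half-open
            neighbors.append(NeighborGene(g["gene_id"], g_start0, g_end0, g["strand"]))
    neighbors.sort(key=lambda n: (n.start, n.gene_id))
    return GeneNeighborhood(
        focal_id=focal_id,
        genome=str(focal["genome"]),
        contig=str(focal["contig"]),
        window_start=win_start,
        window_end=win_end,
        neighbors=neighbors,
    )


def annotate_neighbors(
    neighborhood: GeneNeighborhood,
    hmm_library: Mapping[str, ProfileHMM],
    proteome: Mapping[str, str],
    evalue_max: float = 1e-3,
) -> GeneNeighborhood:
    """Attach the set of domain names hitting each neighbor at E <= evalue_max.

    Domains are a *set* per gene: two copies of a domain in one protein count
    once. The E-value database size is the number of neighbor sequences in
    this call.
    """
    seqs = []
    for n in neighborhood.neighbors:
        if n.gene_id not in proteome:
            raise DataIntegrityError(f"no protein sequence for gene {n.gene_id!r}")
        seqs.append(proteome[n.gene_id])
    neighborhood.hits = {n.gene_id: set() for n in neighborhood.neighbors}
    if not seqs or not hmm_library:
        return neighborhood
    db_size = len(seqs)
    for name in sorted(hmm_library):
        model = hmm_library[name]
        bits = forward_bits_many(model, seqs)
        for n, b in zip(neighborhood.neighbors, bits):
            if evalue(model, float(b), db_size) <= evalue_max:
                neighborhood.hits[n.gene_id].add(name)
    return neighborhood


def domain_presence_table(
    neighborhoods: Sequence[GeneNeighborhood],
    taxonomy: pd.DataFrame,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Domains x clades table of genome-level presence counts.

    cell(domain, clade) = number of distinct genomes in the clade with at
    least one annotated neighbor carrying the domain; multiple focal copies
    in one genome still count once.
    """
    if rank not in taxonomy.columns:
        raise InvalidArgumentError(f"unknown taxonomic rank {rank!r}")
    clade_of = dict(zip(taxonomy["genome"], taxonomy[rank]))
    present: dict[tuple[str, str], set[str]] = {}
    clades = set()
    for nbh in neighborhoods:
        if nbh.genome not in clade_of:
            raise MissingTaxonomyError(nbh.genome)
        clade = clade_of[nbh.genome]
        clades.add(clade)
        for domains in nbh.hits.values():
            for dom in domains:
                present.setdefault((dom, clade), set()).add(nbh.genome)
    domains = sorted({d for d, _ in present})
    clade_list = sorted(clades)
    data = [
        [len(present.get((dom, clade), ())) for clade in clade_list]
        for dom in domains
    ]
    return pd.DataFrame(data, index=pd.Index(domains, name="domain"), columns=clade_list)


def top_domains(table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """Domains ranked by total genome count across clades; ties alphabetical."""
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    totals = table.sum(axis=1)
    ranked = sorted(table.index, key=lambda d: (-totals[d], d))
    return ranked[: min(k, len(ranked))]


def long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Stacked-bar-ready long table: domain, clade, genome_count."""
    out = table.reset_index().melt(id_vars="domain", var_name="clade", value_name="genome_count")
    return out.sort_values(["domain", "clade"]).reset_index(drop=True)
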