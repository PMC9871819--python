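"""The package's headline simulation experiments.

Each function runs one seeded replicate of a study-condition scenario and
returns the measured quantities; they are shared by the test suite and the
reproduction script so both always measure the same thing.
"""

from __future__ import annotations

from typing import Optional

from . import simulate as sim
from .align import progressive_align
from .cterm import build_group_model, cross_search, extract_group_tails, provenance_report
from .phmm import build_from_alignment, calibrate
from .phylo import bootstrap_supports


def _canon(side: frozenset, leaves: set[str]) -> frozenset:
    ref = min(leaves)
    return frozenset(leaves - side) if ref in side else side


def duplication_recovery(
    seed: int, n_taxa: int = 32, n_bootstrap: int = 100, min_support: float = 85.0
) -> dict:
    """One replicate of the paralog-duplication recovery experiment.

    A duplication on the archaeal stem gives every archaeal genome two family
    copies; the bootstrapped NJ tree of all simulated members should contain
    the two paralog clades (leaf sets matching the archaeal species clade),
    each supported at >= ``min_support``.
    """
    tree, _arch, records, _truth = sim.duplication_scenario(n_taxa, seed=seed)
    archaea = {g for g in tree.genomes if tree.taxonomy[g].domain == "Archaea_like"}
    clade_a = frozenset(f"{g}|FtsZ" for g in archaea)
    clade_b = frozenset(f"{g}|FtsZ2" for g in archaea)
    msa = progressive_align(records)
    bt = bootstrap_supports(msa, n_reps=n_bootstrap, seed=seed)
    leaves = set(bt.leaf_ids)
    support = bt.support_by_bipartition()
    sup_a = support.get(_canon(clade_a, leaves))
    sup_b = support.get(_canon(clade_b, leaves))
    ok = sup_a is not None and sup_b is not None and min(sup_a, sup_b) >= min_support
    return {"support_a": sup_a, "support_b": sup_b, "recovered": bool(ok), "n_leaves": len(leaves)}


def provenance_recovery(seed: int, n_taxa: int = 24, calibrate_n: int = 1000) -> dict:
    """One replicate of the C-terminus provenance experiment.

    A CetZ-like group keeps the ancestral archaeal-FtsZ tail; its tail HMM,
    cross-searched against the whole family with no threshold, should flag
    the archaeal-FtsZ stratum (median E <= 1e-2) and neither the
    bacterial-FtsZ nor the tubulin-like strata.
    """
    tree, _arch, records, truth = sim.provenance_scenario(n_taxa, seed=seed)
    seed_msa = sim.nterm_seed_alignment(records, truth, n=12, seed=seed)
    nterm = calibrate(build_from_alignment(seed_msa, name="family_nterm"), seed=seed)
    by_id = {r.seq_id: r for r in records}
    cetz_ids = truth.table.loc[truth.table["paralog"] == "CetZ", "record_id"]
    tails, _skipped = extract_group_tails([by_id[r] for r in cetz_ids], nterm)
    model = build_group_model(tails, name="CetZ_C", seed=seed, calibrate_n=calibrate_n)
    matrix = cross_search([model], records)
    family_of = dict(zip(truth.table["record_id"], truth.table["paralog"]))
    domain_of = {r.seq_id: r.taxonomy.domain for r in records}
    report = provenance_report(matrix, family_of, domain_of)

    def flag(family: str, dom: str) -> Optional[bool]:
        row = report.loc[(report["family"] == family) & (report["tax_domain"] == dom)]
        return bool(row["flagged"].iloc[0]) if len(row) else None

    flag_arc = flag("FtsZ", "Archaea_like")
    flag_bac = flag("FtsZ", "Bacteria_like")
    tub_rows = report.loc[report["family"] == "Tub", "flagged"]
    flag_tub = bool(tub_rows.any()) if len(tub_rows) else None
    ok = flag_arc is True and flag_bac is False and flag_tub is False
    return {
        "flag_archaeal_ftsz": flag_arc,
        "flag_bacterial_ftsz": flag_bac,
        "flag_tubulin_like": flag_tub,
        "recovered": bool(ok),
        "report": report,
    }


def context_contrast(seed: int, n_taxa: int = 20, flank_bp: int = 5000, top_k: int = 25) -> dict:
    """Clade-specific neighborhood recovery: presence table vs the truth tables.

    Returns whether the measured domains-by-clade genome counts equal the
    truth-table recount exactly, and whether the top-k ranking puts every
    template domain first.
    """
    from .context import annotate_neighbors, domain_presence_table, extract_window, top_domains

    tree, records, truth, proteomes, gene_table, tax_table = sim.context_scenario(n_taxa, seed=seed)
    domains = sim.DIVISION_DOMAINS + sim.RIBOSOMAL_DOMAINS
    library = sim.domain_library(domains, seed=seed)
    proteome = {r.seq_id: r.sequence for g in proteomes for r in proteomes[g]}
    neighborhoods = [
        annotate_neighbors(extract_window(gene_table, fid, flank_bp), library, proteome, 1e-3)
        for fid in sorted(truth.neighborhood_class)
    ]
    table = domain_presence_table(neighborhoods, tax_table, rank="domain")

    truth_neighbors = gene_table[~gene_table["truth_domain"].str.startswith("focal")]
    merged = truth_neighbors.merge(tax_table[["genome", "domain"]], on="genome")
    truth_table = (
        merged.groupby(["truth_domain", "domain"])["genome"].nunique().unstack(fill_value=0)
    )
    truth_table = truth_table.reindex(
        index=sorted(set(truth_table.index) | set(table.index)),
        columns=sorted(set(truth_table.columns) | set(table.columns)),
        fill_value=0,
    )
    measured = table.reindex(index=truth_table.index, columns=truth_table.columns, fill_value=0)
    exact = bool((measured.values == truth_table.values).all())
    top = top_domains(table, top_k)
    top_ok = set(top[: len(domains)]) == set(domains)
    return {"exact": exact, "top_ok": bool(top_ok), "table": table, "n_genomes": n_taxa}
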