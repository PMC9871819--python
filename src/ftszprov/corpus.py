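"""Write a complete simulated corpus to disk, ready for the pipeline.

The corpus directory contains everything the analysis stages consume
(proteome FASTA, gene table, taxonomy, seed alignment, neighbor-domain HMM
library, group definitions) plus the ground-truth tables and a ready-made
``pipeline.yaml``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import simulate as sim
from .exceptions import InvalidArgumentError
from .msa import write_fasta
from .pipeline import write_manifest
from .records import write_gene_table, write_taxonomy

SCENARIOS = ("basic", "duplication", "provenance", "context")


def simulate_corpus(
    out: str | Path,
    scenario: str = "duplication",
    n_taxa: int | None = None,
    seed: int = 0,
    calibrate_n: int = 400,
    seed_alignment_size: int = 12,
) -> Path:
    """Simulate a scenario and write the full corpus under ``out``."""
    if scenario not in SCENARIOS:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    if scenario == "duplication":
        tree, arch, records, truth = sim.duplication_scenario(n_taxa or 32, seed)
    elif scenario == "provenance":
        tree, arch, records, truth = sim.provenance_scenario(n_taxa or 24, seed)
    else:  # basic / context: vertical descent only
        tree = sim.simulate_species_tree(n_taxa or 20, seed=seed)
        arch = sim.default_architecture()
        records, truth = sim.evolve_family(tree, arch, sim.EventSchedule([]), seed=seed)

    templates = sim.context_templates()
    proteomes, gene_table, tax_table = sim.emit_genomes(records, truth, tree, templates, seed=seed)

    all_proteins = [rec for genome in sorted(proteomes) for rec in proteomes[genome]]
    write_fasta([(r.seq_id, r.sequence) for r in all_proteins], out / "proteomes.fasta")
    write_gene_table(gene_table, out / "genes.tsv")
    write_taxonomy(tax_table, out / "taxonomy.tsv")
    (out / "species_tree.nwk").write_text(tree.newick() + "\n")

    seed_msa = sim.nterm_seed_alignment(records, truth, n=seed_alignment_size, seed=seed)
    seed_msa.to_fasta(out / "nterm_seed.fasta")

    truth.table.to_csv(out / "truth_records.tsv", sep="\t", index=False, lineterminator="\n")
    truth.event_log.to_csv(out / "events.tsv", sep="\t", index=False, lineterminator="\n")
    nbh = truth.neighborhood_class
    with open(out / "truth_neighborhoods.tsv", "w", newline="\n") as fh:
        fh.write("record_id\tclade_template\n")
        for rid in sorted(nbh):
            fh.write(f"{rid}\t{nbh[rid]}\n")

    groups: dict[str, list[str]] = {}
    for _, row in truth.table.iterrows():
        groups.setdefault(row["paralog"], []).append(row["record_id"])
    from .cterm import write_group_file

    write_group_file(groups, out / "groups.tsv")

    domains = sorted({d for t in templates.values() for d, *_ in t if d != "focal"})
    hmm_dir = out / "hmms"
    hmm_dir.mkdir(exist_ok=True)
    library = sim.domain_library(domains, seed=seed, calibrate_n=calibrate_n)
    for name, model in library.items():
        model.to_text(hmm_dir / f"{name}.hmm")

    pipeline_cfg = {
        "seed": seed,
        "paths": {
            "proteomes": "proteomes.fasta",
            "gene_table": "genes.tsv",
            "taxonomy": "taxonomy.tsv",
            "query_msa": "nterm_seed.fasta",
            "hmm_library": "hmms",
            "groups": "groups.tsv",
        },
    }
    (out / "pipeline.yaml").write_text(yaml.safe_dump(pipeline_cfg, sort_keys=True))
    write_manifest(out, seed)
    return out
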