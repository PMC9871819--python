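"""Synthetic-corpus generator: tree shape, taxonomy cuts, CTMC divergence,
event bookkeeping, genome emission and determinism."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ftszprov.exceptions import ConfigurationError, InvalidArgumentError, ScheduleError
from ftszprov.simulate import (
    DomainArchitecture,
    Event,
    EventSchedule,
    Segment,
    SpeciesTree,
    default_architecture,
    duplication_scenario,
    emit_genomes,
    evolve_family,
    simulate_species_tree,
    sub_model,
)

RANK_CUT_PHYLUM = 0.25


def zero_branch_tree(n, seed=0):
    tree = simulate_species_tree(n, seed=seed)
    for node in tree.root.walk():
        node.length = 0.0
        node.depth = 0.0
    return tree


def two_leaf_tree(branch_length, seed=0):
    tree = simulate_species_tree(2, seed=seed)
    for child in tree.root.children:
        child.length = branch_length
    return tree


# ---------------------------------------------------------------------------
# Species tree


def test_two_leaf_tree_is_ultrametric():
    tree = simulate_species_tree(2, seed=7)
    leaves = tree.root.leaves()
    assert len(leaves) == 2
    assert leaves[0].depth == pytest.approx(leaves[1].depth)


def test_binary_tree_node_count_and_taxonomy():
    tree = simulate_species_tree(16, seed=1)
    nodes = list(tree.root.walk())
    leaves = [n for n in nodes if n.is_leaf()]
    assert len(leaves) == 16
    assert len(nodes) == 2 * 16 - 1
    for genome in tree.genomes:
        tax = tree.taxonomy[genome]
        assert all(tax.rank(r) for r in ("domain", "phylum", "class", "order"))


def test_rejects_fewer_than_two_taxa():
    with pytest.raises(InvalidArgumentError):
        simulate_species_tree(1)


def test_phylum_count_matches_independent_tree_cut():
    """Mean phylum count over replicates vs a direct re-count of branches
    crossing the phylum cut depth."""
    diffs = []
    for seed in range(200):
        tree = simulate_species_tree(64, birth_rate=1.0, seed=seed)
        reported = len({tree.taxonomy[g].phylum for g in tree.genomes})
        crossing = 0
        for node in tree.root.walk():
            parent_depth = node.parent.depth if node.parent else 0.0
            if parent_depth < RANK_CUT_PHYLUM <= node.depth:
                crossing += 1
        diffs.append((reported, crossing))
    mean_reported = np.mean([a for a, _ in diffs])
    mean_crossing = np.mean([b for _, b in diffs])
    assert mean_reported == pytest.approx(mean_crossing, rel=0.2)
    # and per-tree the cut rule is exactly what taxonomy reports
    assert all(a == b for a, b in diffs)


# ---------------------------------------------------------------------------
# Family evolution


def test_zero_branch_lengths_give_identical_sequences():
    tree = zero_branch_tree(2)
    records, truth = evolve_family(tree, default_architecture(), EventSchedule([]), seed=3)
    assert len(records) == 2
    assert records[0].sequence == records[1].sequence


def test_root_duplication_gives_two_copies_everywhere():
    tree = simulate_species_tree(8, seed=2)
    schedule = EventSchedule(
        [Event("duplication", tree.root.node_id, 0.0, {"labels": ("FtsZ", "FtsZ2")}, "d0")]
    )
    records, truth = evolve_family(tree, default_architecture(), schedule, seed=2)
    per_genome = truth.table.groupby("genome").size()
    assert set(per_genome) == {2}
    assert set(truth.table["paralog"]) == {"FtsZ", "FtsZ2"}


def test_truth_table_has_one_row_per_record():
    tree, _arch, records, truth = duplication_scenario(16, seed=4)
    assert sorted(truth.table["record_id"]) == sorted(r.seq_id for r in records)
    assert not truth.table["record_id"].duplicated().any()


def test_schedule_validation_errors():
    tree = simulate_species_tree(8, seed=5)
    with pytest.raises(ScheduleError):
        EventSchedule([Event("duplication", "no_such_node", 0.1)]).validated(tree)
    leaf = tree.root.leaves()[0]
    with pytest.raises(ScheduleError):
        EventSchedule([Event("loss", leaf.node_id, leaf.length + 1.0)]).validated(tree)
    with pytest.raises(ScheduleError):
        EventSchedule([Event("lgt", leaf.node_id, 0.0, {"donor": leaf.node_id})]).validated(tree)


def test_loss_removes_lineage_from_subtree():
    tree = simulate_species_tree(12, seed=6)
    victim = tree.clade_nodes["Archaea_like"]
    schedule = EventSchedule([Event("loss", victim.node_id, 0.0, {"paralog": "FtsZ"}, "l0")])
    records, truth = evolve_family(tree, default_architecture(), schedule, seed=6)
    lost = {lf.node_id for lf in victim.leaves()}
    assert lost.isdisjoint(set(truth.table["genome"]))


def test_focal_count_equals_one_plus_dups_minus_losses():
    tree = simulate_species_tree(16, seed=8)
    arc = tree.clade_nodes["Archaea_like"]
    phyla = sorted({tree.taxonomy[g].phylum for g in tree.genomes})
    loss_clade = tree.clade_nodes[phyla[0]]
    schedule = EventSchedule(
        [
            Event("duplication", arc.node_id, 0.5 * arc.length, {"paralog": "FtsZ", "labels": ("FtsZ", "FtsZ2")}, "d"),
            Event("loss", loss_clade.node_id, 0.5 * loss_clade.length, {"paralog": "FtsZ"}, "l"),
        ]
    )
    records, truth = evolve_family(tree, default_architecture(), schedule, seed=8)
    arc_leaves = {lf.node_id for lf in arc.leaves()}
    loss_leaves = {lf.node_id for lf in loss_clade.leaves()}
    counts = truth.table.groupby("genome").size().to_dict()
    for genome in tree.genomes:
        expected = 1 + (1 if genome in arc_leaves else 0) - (1 if genome in loss_leaves else 0)
        assert counts.get(genome, 0) == expected


def test_cterm_swap_relabels_tail_and_keeps_nterm():
    tree = simulate_species_tree(6, seed=9)
    bac = tree.clade_nodes["Bacteria_like"]
    schedule = EventSchedule(
        [Event("cterm_swap", bac.node_id, 0.5 * bac.length, {"new_tail": "tail_x"}, "s")]
    )
    records, truth = evolve_family(tree, default_architecture(), schedule, seed=9)
    bac_leaves = {lf.node_id for lf in bac.leaves()}
    for _, row in truth.table.iterrows():
        expected = "tail_x" if row["genome"] in bac_leaves else "tail_anc"
        assert row["tail"] == expected


def test_lgt_copies_donor_lineage_into_recipient():
    tree = simulate_species_tree(12, seed=10)
    bac = tree.clade_nodes["Bacteria_like"]
    arc = tree.clade_nodes["Archaea_like"]
    t_event = 0.5 * min(arc.length, bac.length)  # both stems start at the root split
    schedule = EventSchedule(
        [Event("lgt", arc.node_id, t_event, {"donor": bac.node_id, "as_paralog": "FtsZ_x"}, "t")]
    )
    records, truth = evolve_family(tree, default_architecture(), schedule, seed=10)
    xen = truth.table[truth.table["paralog"] == "FtsZ_x"]
    assert len(xen) == len(arc.leaves())
    assert xen["via_lgt"].all()


# ---------------------------------------------------------------------------
# Substitution process vs independent CTMC sampler


def gillespie_identity(rate, branch_length, n_sites, rng):
    """Identity between two lineages diverging for `branch_length` each,
    sampled with an explicit jump-process simulation of the same Q."""
    Q = sub_model().q
    pi = sub_model().pi
    t_eff = branch_length * rate

    def descend(aa):
        t = 0.0
        cur = aa
        while True:
            exit_rate = -Q[cur, cur]
            t += rng.exponential(1.0 / exit_rate)
            if t > t_eff:
                return cur
            probs = Q[cur].copy()
            probs[cur] = 0.0
            probs /= probs.sum()
            cur = int(rng.choice(20, p=probs))
        return cur

    roots = rng.choice(20, size=n_sites, p=pi)
    same = sum(descend(int(a)) == descend(int(a)) for a in roots)
    return same / n_sites


def observed_segment_identities(arch, branch_length, n_seeds):
    obs = {seg.name: [] for seg in arch.segments}
    for seed in range(n_seeds):
        tree = two_leaf_tree(branch_length, seed=seed)
        records, truth = evolve_family(tree, arch, EventSchedule([]), seed=seed)
        ra, rb = records
        ids_a = {int(s): ra.sequence[i] for i, s in enumerate(truth.site_ids[ra.seq_id])}
        ids_b = {int(s): rb.sequence[i] for i, s in enumerate(truth.site_ids[rb.seq_id])}
        shared = set(ids_a) & set(ids_b)
        for seg_idx, seg in enumerate(arch.segments):
            sites = [s for s in shared if truth.site_segment[s] == seg_idx]
            matches = sum(ids_a[s] == ids_b[s] for s in sites)
            obs[seg.name].append(matches / len(sites))
    return {name: float(np.mean(v)) for name, v in obs.items()}


def test_segment_divergence_matches_gillespie_oracle():
    arch = DomainArchitecture(
        [Segment("hi", 120, 0.95), Segment("lo", 120, 0.40)]
    )
    observed = observed_segment_identities(arch, branch_length=0.25, n_seeds=100)
    rng = np.random.default_rng(123)
    for seg in arch.segments:
        expected = gillespie_identity(1.0 - seg.conservation, 0.25, 20000, rng)
        assert observed[seg.name] == pytest.approx(expected, abs=0.02), seg.name


def test_divergence_monotone_in_conservation():
    levels = [0.2, 0.5, 0.8, 0.95]
    arch = DomainArchitecture(
        [Segment(f"c{int(c * 100)}", 60, c) for c in levels]
    )
    observed = observed_segment_identities(arch, branch_length=0.3, n_seeds=50)
    idents = [observed[f"c{int(c * 100)}"] for c in levels]
    rho, _ = spearmanr(levels, idents)
    assert rho == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Genome emission


def test_emit_determinism_byte_identical():
    from ftszprov.simulate import context_scenario

    def render(seed):
        tree, recs, truth, proteomes, gene_table, tax_table = context_scenario(8, seed=seed)
        fasta = "".join(
            f">{r.seq_id}\n{r.sequence}\n" for g in sorted(proteomes) for r in proteomes[g]
        )
        return fasta + gene_table.to_csv() + tax_table.to_csv()

    assert render(5) == render(5)
    assert render(5) != render(6)


def test_template_without_neighbors_single_gene_row():
    tree = simulate_species_tree(4, seed=11)
    records, truth = evolve_family(tree, default_architecture(), EventSchedule([]), seed=11)
    templates = {"Bacteria_like": [("focal", 100)], "Archaea_like": [("focal", 100)]}
    proteomes, gene_table, tax_table = emit_genomes(records, truth, tree, templates, seed=11)
    assert (gene_table.groupby("genome").size() == 1).all()


def test_unknown_clade_tag_rejected():
    tree = simulate_species_tree(4, seed=12)
    records, truth = evolve_family(tree, default_architecture(), EventSchedule([]), seed=12)
    with pytest.raises(ConfigurationError):
        emit_genomes(records, truth, tree, {"NoSuchClade": [("focal", 10)]}, seed=12)


def test_gene_table_coordinates_are_one_based_inclusive():
    tree = simulate_species_tree(4, seed=13)
    records, truth = evolve_family(tree, default_architecture(), EventSchedule([]), seed=13)
    templates = {"Bacteria_like": [("A_dom", 50), ("focal", 50)],
                 "Archaea_like": [("A_dom", 50), ("focal", 50)]}
    proteomes, gene_table, _ = emit_genomes(records, truth, tree, templates, seed=13)
    prot_len = {r.seq_id: len(r.sequence) for g in proteomes for r in proteomes[g]}
    for _, row in gene_table.iterrows():
        assert row["start"] >= 1
        assert row["end"] - row["start"] + 1 == 3 * prot_len[row["gene_id"]]


def test_true_alignment_rows_ungap_to_sequences():
    tree, _arch, records, truth = duplication_scenario(8, seed=14)
    seqs = {r.seq_id: r.sequence for r in records}
    ids = sorted(seqs)[:6]
    aln = truth.true_alignment(ids, sequences=seqs)
    for rid in ids:
        assert aln.ungapped(rid) == seqs[rid]
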