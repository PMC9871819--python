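"""Synthetic corpus generator: a toy genome collection with known history.

The generator emulates, at desk scale, a taxonomically annotated genome
database hosting a modular protein family: a birth-only (Yule) species tree
whose leaves are genomes with a four-rank taxonomy; a family whose members
share a conserved N-terminal domain and carry faster-evolving, potentially
swapped C-terminal segments; ancestral duplications, losses and lateral
transfers; and per-clade gene neighborhoods with distinct domain content.

Ground truth is retained for every downstream stage: per-record paralog and
C-terminus ancestry labels, the exact residue-level homology (site ids
threaded through substitutions and indels, so the true alignment of any
record subset can be reconstructed), segment boundaries, the event log, and
per-gene neighborhood classes.

Substitution model: a fixed empirical exchangeability matrix derived from
BLOSUM62 target odds (s_ij = 2^(score_ij/2)) combined with background
frequencies, scaled to one expected substitution per site per unit branch
length; each segment evolves at rate (1 - conservation). Indels arrive at
0.02 per expected substitution with geometric lengths (p = 0.7) and never
touch the first 10 residues of the N-terminal segment, so the anchored
C-terminus extraction is always well defined.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import BACKGROUND, decode, substitution_matrix
from .exceptions import ConfigurationError, InvalidArgumentError, ScheduleError
from .msa import MultipleAlignment
from .records import Locus, ProteinRecord, Taxonomy

RANK_DEPTHS = {"phylum": 0.25, "class": 0.5, "order": 0.75}
INDEL_RATE_PER_SUB = 0.02
INDEL_GEOM_P = 0.7
NTERM_PROTECTED = 10


# ---------------------------------------------------------------------------
# Species tree


class SNode:
    __slots__ = ("node_id", "length", "children", "parent", "depth")

    def __init__(self, node_id: str, length: float = 0.0):
        self.node_id = node_id
        self.length = length
        self.children: list[SNode] = []
        self.parent: Optional[SNode] = None
        self.depth = 0.0

    def add(self, child: "SNode") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class SpeciesTree:
    root: SNode
    taxonomy: dict[str, Taxonomy]
    clade_nodes: dict[str, SNode]  # clade tag -> node whose stem defines it

    @property
    def genomes(self) -> list[str]:
        return [lf.node_id for lf in self.root.leaves()]

    def node(self, ref: str) -> SNode:
        for n in self.root.walk():
            if n.node_id == ref:
                return n
        if ref.startswith("stem:"):
            tag = ref.split(":", 1)[1]
            if tag in self.clade_nodes:
                return self.clade_nodes[tag]
        if ref in self.clade_nodes:
            return self.clade_nodes[ref]
        raise InvalidArgumentError(f"unknown branch reference {ref!r}")

    def newick(self) -> str:
        def rec(n: SNode) -> str:
            if n.is_leaf():
                return f"{n.node_id}:{n.length:.6g}"
            inner = ",".join(rec(c) for c in n.children)
            return f"({inner}){n.node_id}:{n.length:.6g}"

        return rec(self.root) + ";"


def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> SpeciesTree:
    """Ultrametric Yule tree over ``n_taxa`` genomes with depth-cut taxonomy.

    Branch lengths are rescaled so every root-to-tip path equals 1.0; ranks
    are assigned by cutting the tree at fixed fractions of root height
    (phylum 0.25, class 0.5, order 0.75); the two root children are tagged as
    taxonomic domains, the larger clade as Bacteria_like.
    """
    if n_taxa < 2:
        raise InvalidArgumentError("n_taxa must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    counter = [0]

    def new_internal() -> SNode:
        counter[0] += 1
        return SNode(f"N{counter[0]}")

    root = new_internal()
    a, b = new_internal(), new_internal()
    root.add(a)
    root.add(b)
    tips = [a, b]
    birth_times = {id(a): 0.0, id(b): 0.0}
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        parent.length = t - birth_times.pop(id(parent))
        c1, c2 = new_internal(), new_internal()
        parent.add(c1)
        parent.add(c2)
        for c in (c1, c2):
            tips.append(c)
            birth_times[id(c)] = t
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.length = t_end - birth_times[id(tip)]

    # rescale to unit height, assign depths, rename leaves
    height = t_end if t_end > 0 else 1.0
    for n in root.walk():
        n.length /= height
    root.length = 0.0

    def set_depth(n: SNode, d: float) -> None:
        n.depth = d + n.length
        for c in n.children:
            set_depth(c, n.depth)

    set_depth(root, 0.0)
    leaves = root.leaves()
    for i, lf in enumerate(leaves):
        lf.node_id = f"G{i + 1:03d}"

    # domain tags from the root split: larger clade is Bacteria_like
    kids = sorted(root.children, key=lambda c: (-len(c.leaves()), c.node_id))
    domain_of: dict[str, str] = {}
    clade_nodes = {"Bacteria_like": kids[0]}
    for lf in kids[0].leaves():
        domain_of[lf.node_id] = "Bacteria_like"
    if len(kids) > 1:
        clade_nodes["Archaea_like"] = kids[1]
        for lf in kids[1].leaves():
            domain_of[lf.node_id] = "Archaea_like"

    # rank groups by cutting at fixed depths
    rank_names: dict[str, dict[str, str]] = {}
    prefixes = {"phylum": "p", "class": "c", "order": "o"}
    for rank, cut in RANK_DEPTHS.items():
        groups: dict[str, str] = {}
        k = 0
        for n in root.walk():
            parent_depth = n.parent.depth if n.parent else 0.0
            if parent_depth < cut <= n.depth or (n.is_leaf() and n.depth < cut):
                k += 1
                name = f"{prefixes[rank]}{k:02d}"
                for lf in n.leaves():
                    groups[lf.node_id] = name
                if rank == "phylum":
                    clade_nodes.setdefault(name, n)
        rank_names[rank] = groups

    taxonomy = {
        lf.node_id: Taxonomy(
            domain_of.get(lf.node_id, "Bacteria_like"),
            rank_names["phylum"][lf.node_id],
            rank_names["class"][lf.node_id],
            rank_names["order"][lf.node_id],
        )
        for lf in leaves
    }
    return SpeciesTree(root, taxonomy, clade_nodes)


# ---------------------------------------------------------------------------
# Family architecture and events


@dataclass(frozen=True)
class Segment:
    name: str
    length: int
    conservation: float  # in [0, 1]; evolution rate is (1 - conservation)

    def __post_init__(self) -> None:
        if self.length < 1 or not (0 <= self.conservation <= 1):
            raise InvalidArgumentError(f"bad segment {self.name!r}")


@dataclass
class DomainArchitecture:
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidArgumentError("architecture needs >= 1 segment")


@dataclass(frozen=True)
class Event:
    kind: str  # duplication | loss | lgt | cterm_swap
    branch: str  # node id or clade tag ("stem:Archaea_like")
    time: float  # position on the branch, from its parent end
    params: dict = field(default_factory=dict)
    event_id: str = ""

    KINDS = ("duplication", "loss", "lgt", "cterm_swap")


@dataclass
class EventSchedule:
    events: list[Event]

    def validated(self, tree: SpeciesTree) -> "list[tuple[Event, SNode]]":
        out = []
        for i, ev in enumerate(self.events):
            eid = ev.event_id or f"e{i}"
            if ev.kind not in Event.KINDS:
                raise ScheduleError(eid, f"unknown event kind {ev.kind!r}")
            try:
                node = tree.node(ev.branch)
            except InvalidArgumentError as exc:
                raise ScheduleError(eid, str(exc)) from exc
            if node is not tree.root and not (0 <= ev.time <= node.length + 1e-9):
                raise ScheduleError(eid, f"time {ev.time} outside branch length {node.length}")
            if ev.kind == "lgt":
                try:
                    donor = tree.node(ev.params["donor"])
                except (KeyError, InvalidArgumentError) as exc:
                    raise ScheduleError(eid, f"bad lgt donor: {exc}") from exc
                if donor is node:
                    raise ScheduleError(eid, "lgt donor and recipient must differ")
                t_abs = (node.parent.depth if node.parent else 0.0) + ev.time
                d0 = donor.parent.depth if donor.parent else 0.0
                if not (d0 <= t_abs <= donor.depth + 1e-9):
                    raise ScheduleError(eid, "lgt donor does not coexist with recipient at event time")
            out.append((ev, node))
        return out


# ---------------------------------------------------------------------------
# Substitution machinery


class _SubModel:
    """Reversible 20-state CTMC with eigendecomposed transition matrices."""

    def __init__(self) -> None:
        b62 = substitution_matrix("BLOSUM62")
        s = np.exp2(b62 / 2.0)
        np.fill_diagonal(s, 0.0)
        pi = BACKGROUND
        q = s * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        q /= -(pi * np.diag(q)).sum()  # one substitution per site per unit time
        self.q = q
        self.pi = pi
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self._w, self._u, self._d = w, u, d

    def transition(self, t: float) -> np.ndarray:
        p = (self._u * np.exp(self._w * t)) @ self._u.T
        p = p / self._d[:, None] * self._d[None, :]
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


_SUB_MODEL: Optional[_SubModel] = None


def sub_model() -> _SubModel:
    global _SUB_MODEL
    if _SUB_MODEL is None:
        _SUB_MODEL = _SubModel()
    return _SUB_MODEL


def _sample_states(aas: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    if t <= 0 or len(aas) == 0:
        return aas
    P = sub_model().transition(t)
    cum = P.cumsum(axis=1)
    u = rng.random(len(aas))
    return np.minimum((cum[aas] < u[:, None]).sum(axis=1), 19).astype(np.int8)


# ---------------------------------------------------------------------------
# Gene lineages and truth bookkeeping


class _SegSeq:
    __slots__ = ("ids", "aas")

    def __init__(self, ids: np.ndarray, aas: np.ndarray):
        self.ids = ids
        self.aas = aas

    def copy(self) -> "_SegSeq":
        return _SegSeq(self.ids.copy(), self.aas.copy())


class _Lineage:
    __slots__ = ("paralog", "tail", "segs", "via_lgt")

    def __init__(self, paralog: str, tail: str, segs: list[_SegSeq], via_lgt: bool = False):
        self.paralog = paralog
        self.tail = tail
        self.segs = segs
        self.via_lgt = via_lgt

    def copy(self) -> "_Lineage":
        return _Lineage(self.paralog, self.tail, [s.copy() for s in self.segs], self.via_lgt)


class _SimContext:
    def __init__(self, arch: DomainArchitecture, seed: int):
        self.arch = arch
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        self.next_site = 0
        self.master: list[int] = []  # global column order over all site ids
        self.site_segment: dict[int, int] = {}

    def fresh_segment(self, seg_index: int, after_site: Optional[int]) -> _SegSeq:
        seg = self.arch.segments[seg_index]
        n = seg.length
        ids = np.arange(self.next_site, self.next_site + n, dtype=np.int64)
        self.next_site += n
        aas = self.rng.choice(20, size=n, p=sub_model().pi).astype(np.int8)
        if after_site is None:
            pos = len(self.master)
        else:
            pos = self.master.index(after_site) + 1
        self.master[pos:pos] = ids.tolist()
        for sid in ids:
            self.site_segment[int(sid)] = seg_index
        return _SegSeq(ids, aas)

    def insert_sites(self, n: int, after_site: Optional[int], seg_index: int) -> np.ndarray:
        ids = np.arange(self.next_site, self.next_site + n, dtype=np.int64)
        self.next_site += n
        pos = (self.master.index(after_site) + 1) if after_site is not None else 0
        self.master[pos:pos] = ids.tolist()
        for sid in ids:
            self.site_segment[int(sid)] = seg_index
        return ids


def _evolve_segment(seg: _SegSeq, seg_index: int, t_eff: float, ctx: _SimContext) -> None:
    """Substitutions then indels over an effective time ``t_eff``."""
    if t_eff <= 0 or len(seg.aas) == 0:
        return
    rng = ctx.rng
    seg.aas = _sample_states(seg.aas, t_eff, rng)
    n_exp_subs = len(seg.aas) * t_eff
    n_indels = rng.poisson(INDEL_RATE_PER_SUB * n_exp_subs)
    for _ in range(n_indels):
        length = int(rng.geometric(INDEL_GEOM_P))
        lo = NTERM_PROTECTED if seg_index == 0 else 0
        if len(seg.aas) <= lo + 1:
            continue
        if rng.random() < 0.5:  # insertion after position p-1
            p = int(rng.integers(lo, len(seg.aas)))
            new_ids = ctx.insert_sites(length, int(seg.ids[p]), seg_index)
            new_aas = rng.choice(20, size=length, p=sub_model().pi).astype(np.int8)
            seg.ids = np.concatenate([seg.ids[: p + 1], new_ids, seg.ids[p + 1 :]])
            seg.aas = np.concatenate([seg.aas[: p + 1], new_aas, seg.aas[p + 1 :]])
        else:  # deletion, never emptying the segment
            p = int(rng.integers(lo, len(seg.aas)))
            length = min(length, len(seg.aas) - p)
            if len(seg.aas) - length < max(lo, 1):
                continue
            seg.ids = np.concatenate([seg.ids[:p], seg.ids[p + length :]])
            seg.aas = np.concatenate([seg.aas[:p], seg.aas[p + length :]])


@dataclass
class SimulationTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    table: pd.DataFrame  # record_id, genome, paralog, tail, via_lgt
    event_log: pd.DataFrame
    site_ids: dict[str, np.ndarray]
    seg_bounds: dict[str, list[tuple[str, int, int]]]  # record -> (segment, start, end)
    master: list[int]
    site_segment: dict[int, int]
    neighborhood_class: dict[str, str] = field(default_factory=dict)

    def true_alignment(self, record_ids: Sequence[str], segment: Optional[int] = None,
                       sequences: Optional[dict[str, str]] = None) -> MultipleAlignment:
        """Reconstruct the true alignment of the given records from site ids.

        ``sequences`` maps record id -> residue string (required; the truth
        object stores homology, not letters).
        """
        if sequences is None:
            raise InvalidArgumentError("true_alignment needs the record sequences")
        used: set[int] = set()
        for rid in record_ids:
            ids = self.site_ids[rid]
            for sid in ids:
                if segment is None or self.site_segment[int(sid)] == segment:
                    used.add(int(sid))
        cols = [sid for sid in self.master if sid in used]
        col_pos = {sid: i for i, sid in enumerate(cols)}
        rows = []
        for rid in record_ids:
            row = ["-"] * len(cols)
            seq = sequences[rid]
            for pos, sid in enumerate(self.site_ids[rid]):
                if int(sid) in col_pos:
                    row[col_pos[int(sid)]] = seq[pos]
            rows.append("".join(row))
        return MultipleAlignment(list(record_ids), rows)


def evolve_family(
    tree: SpeciesTree,
    arch: DomainArchitecture,
    schedule: EventSchedule,
    seed: int = 0,
) -> tuple[list[ProteinRecord], SimulationTruth]:
    """Evolve the family down the species tree, applying scheduled events.

    Returns one record per surviving gene copy plus the full truth tables.
    """
    ctx = _SimContext(arch, seed)
    validated = schedule.validated(tree)
    events_by_node: dict[str, list[Event]] = {}
    for ev, node in validated:
        events_by_node.setdefault(node.node_id, []).append(ev)
    for evs in events_by_node.values():
        evs.sort(key=lambda e: e.time)

    root_segs = [ctx.fresh_segment(i, after_site=None) for i in range(len(arch.segments))]
    root_lineage = _Lineage("FtsZ", "tail_anc", root_segs)

    records: list[ProteinRecord] = []
    truth_rows: list[tuple] = []
    site_ids: dict[str, np.ndarray] = {}
    seg_bounds: dict[str, list[tuple[str, int, int]]] = {}
    log_rows: list[tuple] = []
    lgt_checkpoints: dict[str, tuple] = {}  # event_id -> (lineage snapshot, recipient node, remaining time)
    swap_counter = [0]

    def apply_events(node: SNode, lineages: list[_Lineage]) -> list[_Lineage]:
        evs = events_by_node.get(node.node_id, [])
        t_prev = 0.0
        for ev in evs:
            dt = ev.time - t_prev
            for lin in lineages:
                for si, seg in enumerate(lin.segs):
                    rate = 1.0 - arch.segments[si].conservation
                    _evolve_segment(seg, si, dt * rate, ctx)
            t_prev = ev.time
            eid = ev.event_id or ev.kind
            target = ev.params.get("paralog")
            if ev.kind == "duplication":
                new = []
                for lin in lineages:
                    new.append(lin)
                    if target is None or lin.paralog == target:
                        labels = ev.params.get("labels", (lin.paralog, lin.paralog + "_dup"))
                        twin = lin.copy()
                        lin.paralog, twin.paralog = labels
                        new.append(twin)
                        log_rows.append((eid, "duplication", node.node_id, ev.time, target or "*", "->".join(labels)))
                lineages = new
            elif ev.kind == "loss":
                kept = [l for l in lineages if not (target is None or l.paralog == target)]
                lost = [l for l in lineages if (target is None or l.paralog == target)]
                for l in lost:
                    log_rows.append((eid, "loss", node.node_id, ev.time, l.paralog, ""))
                lineages = kept
            elif ev.kind == "cterm_swap":
                for lin in lineages:
                    if target is None or lin.paralog == target:
                        swap_counter[0] += 1
                        new_tail = ev.params.get("new_tail", f"tail_swap{swap_counter[0]}")
                        anchor = int(lin.segs[0].ids[-1])
                        lin.segs = [lin.segs[0]] + [
                            ctx.fresh_segment(i, after_site=anchor)
                            for i in range(1, len(arch.segments))
                        ]
                        lin.tail = new_tail
                        log_rows.append((eid, "cterm_swap", node.node_id, ev.time, lin.paralog, new_tail))
            elif ev.kind == "lgt":
                # recipient side: remember where to graft; the donor snapshot
                # is captured when the donor branch is traversed
                pass
        dt = (node.length if node.parent else 0.0) - t_prev
        if dt > 0:
            for lin in lineages:
                for si, seg in enumerate(lin.segs):
                    rate = 1.0 - arch.segments[si].conservation
                    _evolve_segment(seg, si, dt * rate, ctx)
        return lineages

    # donor checkpoints for lgt: absolute event time on the donor branch
    lgt_events = [(ev, node) for ev, node in validated if ev.kind == "lgt"]

    def emit(leaf: SNode, lineages: list[_Lineage]) -> None:
        for lin in lineages:
            rid = f"{leaf.node_id}|{lin.paralog}"
            seq_ids = np.concatenate([s.ids for s in lin.segs]) if lin.segs else np.empty(0, dtype=np.int64)
            seq_aas = np.concatenate([s.aas for s in lin.segs])
            rec = ProteinRecord(rid, decode(seq_aas), leaf.node_id, taxonomy=tree.taxonomy[leaf.node_id])
            records.append(rec)
            truth_rows.append((rid, leaf.node_id, lin.paralog, lin.tail, lin.via_lgt))
            site_ids[rid] = seq_ids
            bounds = []
            off = 0
            for si, seg in enumerate(lin.segs):
                bounds.append((arch.segments[si].name, off, off + len(seg.aas)))
                off += len(seg.aas)
            seg_bounds[rid] = bounds

    def descend(node: SNode, lineages: list[_Lineage]) -> None:
        lineages = apply_events(node, [l.copy() for l in lineages])
        # capture donor snapshots for lgt events whose donor is this branch
        for ev, recipient in lgt_events:
            donor = tree.node(ev.params["donor"])
            if donor is node:
                eid = ev.event_id or "lgt"
                lgt_checkpoints[eid] = ([l.copy() for l in lineages], recipient, ev)
        if node.is_leaf():
            emit(node, lineages)
        else:
            for child in node.children:
                descend(child, lineages)

    descend(tree.root, [root_lineage])

    # second pass: graft lateral transfers and run their subtrees
    for eid, (snapshot, recipient, ev) in lgt_checkpoints.items():
        target = ev.params.get("paralog")
        grafted = [l for l in snapshot if target is None or l.paralog == target]
        for lin in grafted:
            lin.via_lgt = True
            lin.paralog = ev.params.get("as_paralog", lin.paralog + "_lgt")
        if not grafted:
            raise ScheduleError(eid, f"donor carries no lineage of paralog {target!r}")
        log_rows.append((eid, "lgt", recipient.node_id, ev.time, target or "*", ev.params["donor"]))
        remaining = (recipient.length - ev.time) if recipient.parent else 0.0
        for lin in grafted:
            for si, seg in enumerate(lin.segs):
                rate = 1.0 - arch.segments[si].conservation
                _evolve_segment(seg, si, remaining * rate, ctx)
        if recipient.is_leaf():
            emit(recipient, grafted)
        else:
            for child in recipient.children:
                descend(child, grafted)

    table = pd.DataFrame(truth_rows, columns=["record_id", "genome", "paralog", "tail", "via_lgt"])
    if table["record_id"].duplicated().any():
        raise ScheduleError("schedule", "duplicate record ids; use distinct paralog labels per duplication")
    event_log = pd.DataFrame(log_rows, columns=["event_id", "kind", "branch", "time", "paralog", "detail"])
    truth = SimulationTruth(table, event_log, site_ids, seg_bounds, ctx.master, ctx.site_segment)
    return records, truth


# ---------------------------------------------------------------------------
# Genome emission (neighborhoods, coordinates, FASTA/tables)


def _domain_consensus(domain: str, seed: int, length: int = 60) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(domain.encode()) % (2**31)]))
    return rng.choice(20, size=length, p=BACKGROUND).astype(np.int8)


def _noisy_copy(consensus: np.ndarray, mutation: float, rng: np.random.Generator) -> str:
    aas = consensus.copy()
    flip = rng.random(len(aas)) < mutation
    aas[flip] = rng.choice(20, size=int(flip.sum()), p=BACKGROUND)
    return decode(aas)


def emit_genomes(
    records: Sequence[ProteinRecord],
    truth: SimulationTruth,
    tree: SpeciesTree,
    neighborhood_templates: dict[str, list[tuple]],
    seed: int = 0,
    domain_length: int = 60,
    neighbor_noise: float = 0.1,
) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame, pd.DataFrame]:
    """Embed each focal gene in its clade's template neighborhood.

    Template entries are ``(domain_id, gap_bp)`` or ``(domain_id, gap_bp,
    strand)``, with the literal entry ``"focal"`` marking the family gene;
    the gap precedes the gene. Strands alternate +/- unless given. Each
    genome is one contig; coordinates are 0-based half-open internally and
    1-based inclusive in written tables. Returns (per-genome protein records
    including neighbors, gene table, taxonomy table) and fills in
    ``truth.neighborhood_class``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    by_genome: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome, []).append(rec)
    gene_rows: list[tuple] = []
    proteomes: dict[str, list[ProteinRecord]] = {}
    for genome in sorted(by_genome):
        tax = tree.taxonomy[genome]
        tag = None
        for cand in (tax.domain, tax.phylum, tax.klass, tax.order):
            if cand in neighborhood_templates:
                tag = cand
                break
        if tag is None:
            if "default" in neighborhood_templates:
                tag = "default"
            else:
                raise ConfigurationError(f"no neighborhood template matches genome {genome!r}")
        template = neighborhood_templates[tag]
        contig = f"{genome}_c1"
        cursor = 0
        out: list[ProteinRecord] = []
        nidx = 0
        focal_list = sorted(by_genome[genome], key=lambda r: r.seq_id)
        for focal in focal_list:
            truth.neighborhood_class[focal.seq_id] = tag
            for j, entry in enumerate(template):
                domain_id, gap = entry[0], int(entry[1])
                strand = entry[2] if len(entry) > 2 else ("+" if j % 2 == 0 else "-")
                cursor += gap
                if domain_id == "focal":
                    prot, gid, tdom = focal.sequence, focal.seq_id, "focal:" + truth_paralog(truth, focal.seq_id)
                    rec = focal
                    rec.locus = Locus(contig, cursor, cursor + 3 * len(prot), strand)
                else:
                    nidx += 1
                    cons = _domain_consensus(domain_id, seed, domain_length)
                    prot = _noisy_copy(cons, neighbor_noise, rng)
                    gid, tdom = f"{genome}|n{nidx}", domain_id
                    rec = ProteinRecord(gid, prot, genome, taxonomy=tax,
                                        locus=Locus(contig, cursor, cursor + 3 * len(prot), strand))
                gene_rows.append((genome, contig, gid, cursor + 1, cursor + 3 * len(prot), strand, tdom))
                cursor += 3 * len(prot)
                out.append(rec)
        proteomes[genome] = out
    gene_table = pd.DataFrame(
        gene_rows, columns=["genome", "contig", "gene_id", "start", "end", "strand", "truth_domain"]
    )
    tax_table = pd.DataFrame(
        [
            (g, t.domain, t.phylum, t.klass, t.order)
            for g, t in sorted(tree.taxonomy.items())
            if g in proteomes
        ],
        columns=["genome", "domain", "phylum", "class", "order"],
    )
    return proteomes, gene_table, tax_table


def truth_paralog(truth: SimulationTruth, record_id: str) -> str:
    row = truth.table.loc[truth.table["record_id"] == record_id]
    return row["paralog"].iloc[0] if len(row) else "?"


def domain_library(
    domains: Sequence[str],
    seed: int = 0,
    n_train: int = 8,
    domain_length: int = 60,
    mutation: float = 0.1,
    calibrate_n: int = 400,
) -> dict:
    """Calibrated profile HMMs for the simulator's neighbor domains.

    Each model is trained on noisy copies of the domain's consensus; this is
    the toy analog of an external domain-profile library.
    """
    from .phmm import build_from_alignment, calibrate

    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    out = {}
    for domain in domains:
        cons = _domain_consensus(domain, seed, domain_length)
        rows = [_noisy_copy(cons, mutation, rng) for _ in range(n_train)]
        msa = MultipleAlignment([f"t{i}" for i in range(n_train)], rows)
        model = build_from_alignment(msa, occupancy=0.5, name=domain)
        out[domain] = calibrate(model, n_random=max(calibrate_n, 100),
                                seed=int(rng.integers(2**31)))
    return out


# ---------------------------------------------------------------------------
# Ready-made study scenarios


def simulate_deep_split_tree(
    n_taxa: int,
    seed: int = 0,
    min_minor_leaves: int = 5,
    min_stem: float = 0.15,
    max_tries: int = 50,
) -> SpeciesTree:
    """A Yule tree constrained to a deep, non-degenerate root split.

    The scenarios emulate two prokaryotic domains separated by an ancient
    divergence: the minority root clade must hold at least
    ``min_minor_leaves`` genomes and both stems must span at least
    ``min_stem`` of the unit root height. Draws are repeated with derived
    sub-seeds (deterministically) until the constraint holds; the best draw
    is kept if none does.
    """
    best, best_score = None, -1.0
    for attempt in range(max_tries):
        sub = seed if attempt == 0 else int(
            np.random.SeedSequence([seed, 97, attempt]).generate_state(1)[0] % (2**31)
        )
        tree = simulate_species_tree(n_taxa, seed=sub)
        kids = tree.root.children
        minor = min(len(k.leaves()) for k in kids)
        stem = min(k.length for k in kids)
        if minor >= min_minor_leaves and stem >= min_stem:
            return tree
        score = min(minor / max(min_minor_leaves, 1), stem / min_stem)
        if score > best_score:
            best, best_score = tree, score
    return best


def default_architecture() -> DomainArchitecture:
    """One conserved N-terminal GTPase-like domain plus a variable C-terminal tail.

    Dimensions follow the real family: the shared N-terminal domain spans
    roughly 200 residues and the lineage-specific C-terminal region another
    ~100, giving members of ~300 residues.
    """
    return DomainArchitecture(
        [Segment("tubulin_like", 200, 0.85), Segment("cterm_tail", 100, 0.55)]
    )


def duplication_scenario(n_taxa: int = 32, seed: int = 0):
    """A focal-gene duplication at the top of the archaeal stem.

    The duplication precedes the archaeal radiation (it sits at the start of
    the stem, directly after the domain split), so every archaeal genome
    carries two paralogs (FtsZ and FtsZ2) whose clades both mirror the
    archaeal species clade.
    """
    tree = simulate_deep_split_tree(n_taxa, seed=seed)
    arch = default_architecture()
    stem = tree.clade_nodes["Archaea_like"]
    schedule = EventSchedule(
        [
            Event("duplication", stem.node_id, 0.0,
                  {"paralog": "FtsZ", "labels": ("FtsZ", "FtsZ2")}, "dup_arc"),
        ]
    )
    records, truth = evolve_family(tree, arch, schedule, seed=seed)
    return tree, arch, records, truth


def provenance_scenario(n_taxa: int = 24, seed: int = 0):
    """Paralog groups with distinct C-terminus ancestries.

    The root family splits into FtsZ and a tubulin-like paralog whose tail is
    replaced at the root; the bacterial FtsZ tail is replaced on the
    bacterial stem; a duplication on the archaeal stem creates a CetZ-like
    group that *keeps* the ancestral (archaeal-FtsZ) tail. The C-terminus
    cross-search should therefore link CetZ to archaeal FtsZ and to nothing
    else.
    """
    tree = simulate_deep_split_tree(n_taxa, seed=seed, min_minor_leaves=4)
    arch = default_architecture()
    bac = tree.clade_nodes["Bacteria_like"]
    arc = tree.clade_nodes["Archaea_like"]
    root_id = tree.root.node_id
    schedule = EventSchedule(
        [
            Event("duplication", root_id, 0.0, {"paralog": "FtsZ", "labels": ("FtsZ", "Tub")}, "dup_root"),
            Event("cterm_swap", root_id, 0.0, {"paralog": "Tub", "new_tail": "tail_tub"}, "swap_tub"),
            Event("cterm_swap", bac.node_id, 0.3 * bac.length,
                  {"paralog": "FtsZ", "new_tail": "tail_bac"}, "swap_bac"),
            Event("duplication", arc.node_id, 0.5 * arc.length,
                  {"paralog": "FtsZ", "labels": ("FtsZ", "CetZ")}, "dup_cetz"),
        ]
    )
    records, truth = evolve_family(tree, arch, schedule, seed=seed)
    return tree, arch, records, truth


DIVISION_DOMAINS = ["FtsA_like", "SepF_like", "MurB_like", "DdlB_like"]
RIBOSOMAL_DOMAINS = ["RpL7_like", "RpS9_like", "SecE_like"]


def context_templates() -> dict[str, list[tuple]]:
    """Division-cluster neighborhood for bacteria, ribosomal for archaea."""
    bac = [(DIVISION_DOMAINS[0], 150), (DIVISION_DOMAINS[1], 120), ("focal", 200),
           (DIVISION_DOMAINS[2], 180), (DIVISION_DOMAINS[3], 90)]
    arc = [(RIBOSOMAL_DOMAINS[0], 140), ("focal", 160), (RIBOSOMAL_DOMAINS[1], 110),
           (RIBOSOMAL_DOMAINS[2], 130)]
    return {"Bacteria_like": bac, "Archaea_like": arc}


def context_scenario(n_taxa: int = 20, seed: int = 0):
    """Clade-specific neighborhoods around a single-copy focal gene."""
    tree = simulate_species_tree(n_taxa, seed=seed)
    arch = default_architecture()
    records, truth = evolve_family(tree, arch, EventSchedule([]), seed=seed)
    proteomes, gene_table, tax_table = emit_genomes(
        records, truth, tree, context_templates(), seed=seed
    )
    return tree, records, truth, proteomes, gene_table, tax_table


# ---------------------------------------------------------------------------
# Seed alignment for the collection stage


def nterm_seed_alignment(
    records: Sequence[ProteinRecord], truth: SimulationTruth, n: int = 12, seed: int = 0
) -> MultipleAlignment:
    """True alignment of the shared N-terminal segment over a record sample.

    This is the toy analog of a curated external domain profile used to seed
    the homolog collection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    ids = sorted(r.seq_id for r in records)
    pick = sorted(rng.choice(len(ids), size=min(n, len(ids)), replace=False).tolist())
    chosen = [ids[i] for i in pick]
    seqs = {r.seq_id: r.sequence for r in records}
    return truth.true_alignment(chosen, segment=0, sequences=seqs)
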