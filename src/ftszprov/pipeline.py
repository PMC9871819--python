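"""End-to-end pipeline: config validation, stage orchestration, manifests.

Stages run in a fixed order (collect, curate, align, tree, context, cterm),
each writing its artifacts plus a ``manifest.json`` (sha256 checksums, the
stage seed, package version) into its own subdirectory of the output
directory. Per-stage seeds are derived from the root seed and a fixed stage
index, so toggling one stage never shifts another stage's random stream and
reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigurationError, PipelineError
from .msa import MultipleAlignment, read_fasta, write_fasta
from .records import ProteinRecord, read_gene_table, read_taxonomy, taxonomy_lookup

log = logging.getLogger("ftszprov")

STAGES = ("collect", "curate", "align", "tree", "context", "cterm")
STAGE_SEED_INDEX = {name: i + 1 for i, name in enumerate(STAGES)}

# every threshold from the study's methods appears here as a default
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "paths": {
        "proteomes": None,
        "gene_table": None,
        "taxonomy": None,
        "query_msa": None,
        "hmm_library": None,  # directory of .hmm text files (context stage)
        "groups": None,  # group -> member TSV (cterm stage)
        "include_ids": None,  # optional file: ids forced through subsampling
    },
    "collect": {"evalue": 1e-3},
    "curate": {"coverage": 0.6, "redundancy": True, "one_per_order": False},
    "trim": {"method": "gt", "gt": 0.2, "entropy_h": 0.55, "entropy_matrix": "BLOSUM45"},
    "tree": {"bootstrap": 100, "collapse": 85.0, "midpoint": True},
    "context": {"flank": 5000, "evalue": 1e-3, "top_k": 25, "rank": "phylum"},
    "cterm": {"gt": 0.1, "min_tail": 20, "calibrate_n": 1000},
    "stages": list(STAGES),
}

_RANGES = {
    ("collect", "evalue"): (0.0, None),
    ("curate", "coverage"): (0.0, 1.0),
    ("trim", "gt"): (0.0, 1.0),
    ("trim", "entropy_h"): (0.0, 1.0),
    ("tree", "bootstrap"): (1, None),
    ("tree", "collapse"): (0.0, 100.0),
    ("context", "flank"): (1, None),
    ("context", "top_k"): (1, None),
    ("cterm", "gt"): (0.0, 1.0),
    ("cterm", "min_tail"): (1, None),
    ("cterm", "calibrate_n"): (100, None),
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and isinstance(uval, dict):
                out[key] = _merge(dval, uval, f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown config key {path}{sorted(unknown)[0]!r}")
    return out


def validate_config(source: str | Path | dict, base_dir: Optional[Path] = None) -> dict:
    """Parse, default, and range-check a pipeline config.

    ``source`` may be a YAML path or an already-parsed mapping. Unknown keys
    and out-of-range thresholds are errors; referenced paths must exist.
    """
    if isinstance(source, dict):
        user = source
        base = base_dir or Path(".")
    else:
        path = Path(source)
        user = yaml.safe_load(path.read_text()) or {}
        base = base_dir or path.parent
    if not isinstance(user, dict):
        raise ConfigurationError("config must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    for (section, key), (lo, hi) in _RANGES.items():
        val = cfg[section][key]
        if val is None or (lo is not None and val < lo) or (hi is not None and val > hi):
            raise ConfigurationError(f"{section}.{key}={val!r} outside [{lo}, {hi}]")
    if cfg["trim"]["method"] not in ("gt", "entropy"):
        raise ConfigurationError(f"trim.method must be gt or entropy, got {cfg['trim']['method']!r}")
    unknown_stages = set(cfg["stages"]) - set(STAGES)
    if unknown_stages:
        raise ConfigurationError(f"unknown stage {sorted(unknown_stages)[0]!r}")
    resolved = {}
    for key, val in cfg["paths"].items():
        if val is None:
            resolved[key] = None
            continue
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigurationError(f"paths.{key}: {p} does not exist")
        resolved[key] = p
    cfg["paths"] = resolved
    for required in ("proteomes", "gene_table", "taxonomy", "query_msa"):
        if cfg["paths"][required] is None and set(cfg["stages"]) & {"collect", "curate", "align", "tree"}:
            raise ConfigurationError(f"paths.{required} is required")
    return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(root_seed), STAGE_SEED_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Input loading


def load_collection(cfg: dict) -> list[ProteinRecord]:
    """Proteome FASTA + gene table + taxonomy -> linked protein records."""
    genes = read_gene_table(cfg["paths"]["gene_table"])
    tax = taxonomy_lookup(read_taxonomy(cfg["paths"]["taxonomy"]))
    genome_of = dict(zip(genes["gene_id"], genes["genome"]))
    records = []
    for rid, seq in read_fasta(cfg["paths"]["proteomes"]):
        genome = genome_of.get(rid, rid.split("|")[0])
        records.append(ProteinRecord(rid, seq, genome, taxonomy=tax.get(genome)))
    return records


# ---------------------------------------------------------------------------
# Manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(stage_dir: Path, seed: int) -> Path:
    files = sorted(
        p for p in stage_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": seed,
        "files": {str(p.relative_to(stage_dir)): _sha256(p) for p in files},
    }
    out = stage_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


# ---------------------------------------------------------------------------
# Stages


def stage_collect(cfg: dict, out: Path) -> dict:
    from .phmm import build_from_alignment, calibrate, hits_to_table, search

    seed = stage_seed(cfg["seed"], "collect")
    records = load_collection(cfg)
    seed_msa = MultipleAlignment.from_fasta(cfg["paths"]["query_msa"])
    model = calibrate(build_from_alignment(seed_msa, name="family_nterm"), seed=seed)
    hits = search(model, records, evalue_max=cfg["collect"]["evalue"])
    hit_ids = {h.target_id for h in hits}
    collected = [r for r in records if r.seq_id in hit_ids]
    sdir = out / "collect"
    sdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.seq_id, r.sequence) for r in collected], sdir / "collected.fasta")
    hits_to_table(hits, sdir / "hits.tsv")
    model.to_text(sdir / "family_nterm.hmm")
    write_manifest(sdir, seed)
    return {"collected": collected, "nterm_model": model, "all_records": records}


def stage_curate(cfg: dict, out: Path, state: dict) -> dict:
    from .align import progressive_align
    from .curate import coverage_filter, one_per_order, reduce_redundancy_by_class

    seed = stage_seed(cfg["seed"], "curate")
    collected = state["collected"]
    msa = progressive_align(collected)
    kept_ids = set(coverage_filter(msa, cfg["curate"]["coverage"]))
    kept = [r for r in collected if r.seq_id in kept_ids]
    if cfg["curate"]["redundancy"]:
        kept = reduce_redundancy_by_class(kept)
    if cfg["curate"]["one_per_order"]:
        include = []
        if cfg["paths"]["include_ids"]:
            include = [ln.strip() for ln in Path(cfg["paths"]["include_ids"]).read_text().splitlines() if ln.strip()]
        kept = one_per_order(kept, seed=seed, include_ids=include)
    sdir = out / "curate"
    sdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.seq_id, r.sequence) for r in kept], sdir / "curated.fasta")
    write_manifest(sdir, seed)
    return {"curated": kept}


def stage_align(cfg: dict, out: Path, state: dict) -> dict:
    from .align import progressive_align
    from .curate import trim_entropy, trim_gap_threshold, trim_report

    seed = stage_seed(cfg["seed"], "align")
    curated = state["curated"]
    msa = progressive_align(curated)
    if cfg["trim"]["method"] == "gt":
        trimmed = trim_gap_threshold(msa, cfg["trim"]["gt"])
    else:
        trimmed = trim_entropy(msa, cfg["trim"]["entropy_h"], cfg["trim"]["entropy_matrix"])
    sdir = out / "align"
    sdir.mkdir(parents=True, exist_ok=True)
    msa.to_fasta(sdir / "family_aln.fasta")
    trimmed.to_fasta(sdir / "family_trimmed.fasta")
    trim_report(msa, trimmed).to_csv(sdir / "trim_report.tsv", sep="\t", index=False, lineterminator="\n")
    write_manifest(sdir, seed)
    return {"msa": msa, "trimmed": trimmed}


def stage_tree(cfg: dict, out: Path, state: dict) -> dict:
    from .phylo import bootstrap_supports, collapse_low_support, midpoint_root, tree_to_itol_annotations

    seed = stage_seed(cfg["seed"], "tree")
    trimmed = state["trimmed"]
    tree = bootstrap_supports(trimmed, n_reps=cfg["tree"]["bootstrap"], seed=seed)
    sdir = out / "tree"
    sdir.mkdir(parents=True, exist_ok=True)
    tree.write_newick(sdir / "nj_bootstrap.nwk")
    final = tree
    if cfg["tree"]["midpoint"]:
        final = midpoint_root(final)
        final.write_newick(sdir / "nj_midpoint.nwk")
    if cfg["tree"]["collapse"] > 0:
        final = collapse_low_support(final, cfg["tree"]["collapse"])
        final.write_newick(sdir / "nj_collapsed.nwk")
    curated = {r.seq_id: r for r in state["curated"]}
    classes = {
        rid: (curated[rid].taxonomy.phylum if curated[rid].taxonomy else "?")
        for rid in final.leaf_ids
    }
    (sdir / "itol_phylum.txt").write_text(tree_to_itol_annotations(final, classes))
    write_manifest(sdir, seed)
    return {"tree": tree, "final_tree": final}


def stage_context(cfg: dict, out: Path, state: dict) -> dict:
    from .context import annotate_neighbors, domain_presence_table, extract_window, long_format, top_domains
    from .phmm import ProfileHMM

    seed = stage_seed(cfg["seed"], "context")
    genes = read_gene_table(cfg["paths"]["gene_table"])
    taxonomy = read_taxonomy(cfg["paths"]["taxonomy"])
    library: dict[str, ProfileHMM] = {}
    if cfg["paths"]["hmm_library"]:
        for p in sorted(Path(cfg["paths"]["hmm_library"]).glob("*.hmm")):
            model = ProfileHMM.from_text(p)
            library[model.name] = model
    proteome = {rid: seq for rid, seq in read_fasta(cfg["paths"]["proteomes"])}
    focal_ids = sorted(r.seq_id for r in state["collected"])
    neighborhoods = []
    for fid in focal_ids:
        if not (genes["gene_id"] == fid).any():
            continue  # collected protein without genomic coordinates
        nbh = extract_window(genes, fid, cfg["context"]["flank"])
        neighborhoods.append(annotate_neighbors(nbh, library, proteome, cfg["context"]["evalue"]))
    table = domain_presence_table(neighborhoods, taxonomy, rank=cfg["context"]["rank"])
    top = top_domains(table, cfg["context"]["top_k"])
    sdir = out / "context"
    sdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(sdir / "domain_presence.tsv", sep="\t", lineterminator="\n")
    long_format(table).to_csv(sdir / "domain_presence_long.tsv", sep="\t", index=False, lineterminator="\n")
    (sdir / "top_domains.txt").write_text("\n".join(top) + "\n")
    write_manifest(sdir, seed)
    return {"context_table": table, "top_domains": top, "neighborhoods": neighborhoods}


def stage_cterm(cfg: dict, out: Path, state: dict) -> dict:
    from .cterm import (
        build_group_model,
        cross_search,
        extract_group_tails,
        map_hits_to_tree,
        provenance_report,
        read_group_file,
    )
    from .exceptions import GroupTooSmallError

    seed = stage_seed(cfg["seed"], "cterm")
    if not cfg["paths"]["groups"]:
        raise PipelineError("cterm", "paths.groups is required for the cterm stage")
    groups = read_group_file(cfg["paths"]["groups"])
    collected = state["collected"]
    by_id = {r.seq_id: r for r in collected}
    nterm_model = state["nterm_model"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    models = []
    skipped_all: dict[str, list[str]] = {}
    for gname in sorted(groups):
        members = [by_id[m] for m in groups[gname] if m in by_id]
        tails, skipped = extract_group_tails(members, nterm_model, cfg["cterm"]["min_tail"])
        skipped_all[gname] = skipped
        try:
            models.append(
                build_group_model(
                    tails, name=f"{gname}_C", gt=cfg["cterm"]["gt"],
                    seed=int(rng.integers(2**31)), calibrate_n=cfg["cterm"]["calibrate_n"],
                )
            )
        except GroupTooSmallError as exc:
            log.warning("cterm: %s", exc)
    # cross-search over the tree's leaf set so hits map onto the tree
    targets = state.get("curated", collected)
    matrix = cross_search(models, targets)
    sdir = out / "cterm"
    sdir.mkdir(parents=True, exist_ok=True)
    for model in models:
        model.to_text(sdir / f"{model.name}.hmm")
    matrix.to_tsv(sdir / "hit_matrix.tsv")
    if "final_tree" in state:
        leaf_set = set(state["final_tree"].leaf_ids)
        sub = _submatrix(matrix, [t for t in matrix.targets if t in leaf_set])
        (sdir / "itol_heatmap.txt").write_text(map_hits_to_tree(state["final_tree"], sub))
    family_of = {m: g for g, ms in groups.items() for m in ms}
    domain_of = {
        r.seq_id: (r.taxonomy.domain if r.taxonomy else "?") for r in collected
    }
    report = provenance_report(matrix, family_of, domain_of)
    report_out = report.copy()
    for col in ("median_evalue", "min_evalue", "hit_frac"):
        report_out[col] = report_out[col].map(lambda v: "%.6g" % v)
    report_out.to_csv(sdir / "provenance_report.tsv", sep="\t", index=False, lineterminator="\n")
    write_manifest(sdir, seed)
    return {"hit_matrix": matrix, "provenance": report}


def _submatrix(matrix, targets):
    from .cterm import HitMatrix

    idx = [matrix.targets.index(t) for t in targets]
    return HitMatrix(matrix.models, targets, matrix.evalues[:, idx], matrix.db_size)


_STAGE_FUNCS = {
    "collect": stage_collect,
    "curate": stage_curate,
    "align": stage_align,
    "tree": stage_tree,
    "context": stage_context,
    "cterm": stage_cterm,
}

_STAGE_DEPS = {
    "curate": ("collected",),
    "align": ("curated",),
    "tree": ("trimmed",),
    "context": ("collected",),
    "cterm": ("collected", "nterm_model"),
}


def run_pipeline(cfg: dict, out: str | Path) -> Path:
    """Run the configured stages in order; halt on the first failure.

    Each stage writes its artifacts and manifest under ``out/<stage>/``.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in cfg["stages"]:
                continue
            missing = [d for d in _STAGE_DEPS.get(stage, ()) if d not in state]
            if missing:
                raise PipelineError(stage, f"requires earlier stage output {missing[0]!r}")
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            try:
                if stage == "collect":
                    state.update(_STAGE_FUNCS[stage](cfg, out))
                else:
                    state.update(_STAGE_FUNCS[stage](cfg, out, state))
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
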