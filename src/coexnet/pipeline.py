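"""End-to-end orchestration: filter → QC → associate → threshold → vicinity.

``run_pipeline`` executes the full analysis from a raw count file to the
selected co-expression network and its vicinity networks, writing every
stage's output as plain text (TSV / Newick / GraphML / JSON) plus a run
manifest with record counts and SHA-256 digests, so identical inputs and
config yield byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import expression as ex
from . import sample_qc as qc
from .association import spearman_matrix
from .network import (
    DEFAULT_THRESHOLD_GRID,
    SelectionCriteria,
    metrics_table,
    refine_thresholds,
    select_threshold,
    threshold_adjacency,
    write_edge_list,
)
from .vicinity import (
    export_vn,
    expression_profiles,
    extract_vicinity,
    filter_vns,
    vn_summary,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("coexnet")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    counts: str
    groups: str
    seeds: str
    out_dir: str
    min_cpm: float = 5.0
    cut_height: float = 0.4
    linkage: str = "complete"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    vn_metric: str = "density"
    vn_min: float = 0.5
    recompute_cpm_after_qc: bool = True
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = SelectionCriteria(**raw["criteria"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_seed_list(path: str | Path) -> list[str]:
    seeds = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            seeds.append(line.split()[0])
    return seeds


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and return the manifest (also written to disk).

    Stages: read counts → cpm + expression filter → per-group Jaccard outlier
    QC (outliers dropped, cpm optionally recomputed on the surviving samples)
    → Spearman association → threshold refinement + selection → vicinity
    networks for the seed genes.  Any stage failure aborts with a
    stage-named error.
    """
    for label, p in (("counts", cfg.counts), ("groups", cfg.groups),
                     ("seeds", cfg.seeds)):
        if not Path(p).exists():
            raise FileNotFoundError(f"[{label}] input file not found: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.echo(), "stages": {}}
    outputs: dict[str, Path] = {}

    def stage(name):
        log.info("[%s] starting", name)
        return name

    # ---- read -------------------------------------------------------------
    name = stage("read")
    try:
        cm = ex.read_counts(cfg.counts, cfg.groups)
    except Exception as err:
        raise RuntimeError(f"[read] {err}") from err
    seed_genes = _read_seed_list(cfg.seeds)
    manifest["stages"][name] = {
        "genes_in": len(cm.gene_ids),
        "samples_in": len(cm.sample_ids),
        "seed_genes": len(seed_genes),
    }

    # ---- filter -----------------------------------------------------------
    name = stage("filter")
    try:
        nm = ex.cpm_normalize(cm)
        retained, nm_f = ex.filter_low_expression(nm, cfg.min_cpm)
    except Exception as err:
        raise RuntimeError(f"[filter] {err}") from err
    manifest["stages"][name] = {
        "min_cpm": cfg.min_cpm,
        "genes_after_filter": len(retained),
    }

    # ---- qc ---------------------------------------------------------------
    name = stage("qc")
    try:
        flagged: set[str] = set()
        newicks = {}
        for grp in sorted(set(nm_f.groups.values())):
            members = [s for s in nm_f.sample_ids if nm_f.groups[s] == grp]
            if len(members) < 2:
                continue
            dm = qc.sample_distances(nm_f.subset_samples(members))
            dend = qc.cluster_samples(dm, cfg.linkage)
            newicks[grp] = qc.dendrogram_to_newick(dend)
            flagged |= qc.flag_outliers(dend, cfg.cut_height)
            dm.to_frame().to_csv(out / f"distance_{grp}.tsv", sep="\t",
                                 float_format="%.6g")
            (out / f"dendrogram_{grp}.nwk").write_text(newicks[grp] + "\n")
        (out / "flagged_samples.txt").write_text(
            "".join(f"{s}\n" for s in sorted(flagged)))
        outputs["flagged_samples"] = out / "flagged_samples.txt"
        if flagged:
            cm = cm.drop_samples(flagged)
            if cfg.recompute_cpm_after_qc:
                nm = ex.cpm_normalize(cm)
                retained, nm_f = ex.filter_low_expression(nm, cfg.min_cpm)
            else:
                nm_f = nm_f.subset_samples(
                    [s for s in nm_f.sample_ids if s not in flagged])
        mds = qc.leading_logfc_mds(nm_f)
        with open(out / "mds_coordinates.tsv", "w") as fh:
            fh.write("sample\tgroup\tdim1\tdim2\n")
            for sid, (x, y) in zip(mds.sample_ids, mds.coordinates):
                fh.write(f"{sid}\t{nm_f.groups[sid]}\t{x:.6g}\t{y:.6g}\n")
        outputs["mds"] = out / "mds_coordinates.tsv"
        ex.write_cpm(nm_f, out / "filtered_cpm.tsv")
        outputs["filtered_cpm"] = out / "filtered_cpm.tsv"
    except Exception as err:
        raise RuntimeError(f"[qc] {err}") from err
    manifest["stages"][name] = {
        "outliers_flagged": sorted(flagged),
        "samples_after_qc": len(nm_f.sample_ids),
        "genes_after_filter": len(nm_f.gene_ids),
    }

    # ---- associate --------------------------------------------------------
    name = stage("associate")
    try:
        am = spearman_matrix(nm_f)
    except Exception as err:
        raise RuntimeError(f"[associate] {err}") from err
    manifest["stages"][name] = {"genes_correlated": len(am.gene_ids)}

    # ---- build ------------------------------------------------------------
    name = stage("build")
    try:
        rows = refine_thresholds(am, cfg.thresholds)
        table = metrics_table(rows)
        table.to_csv(out / "refinement_table.tsv", sep="\t", index=False,
                     float_format="%.6g")
        outputs["refinement_table"] = out / "refinement_table.tsv"
        sel = select_threshold(rows, cfg.criteria)
        net = threshold_adjacency(am, sel.metrics.threshold)
        write_edge_list(net, out / "network_edges.tsv")
        outputs["network_edges"] = out / "network_edges.tsv"
    except Exception as err:
        raise RuntimeError(f"[build] {err}") from err
    manifest["stages"][name] = {
        "chosen_threshold": sel.metrics.threshold,
        "selection_relaxed": sel.relaxed,
        "criteria_satisfied": sel.n_satisfied,
        "n_edges": sel.metrics.n_edges,
        "n_used": sel.metrics.n_used,
    }

    # ---- vicinity ---------------------------------------------------------
    name = stage("vicinity")
    try:
        universe = set(net.gene_ids)
        vns = []
        skipped = [s for s in seed_genes if s not in universe]
        for seed in seed_genes:
            if seed in universe:
                vns.append(extract_vicinity(net, seed))
        kept = filter_vns(vns, cfg.vn_metric, cfg.vn_min)
        summary = vn_summary(vns, kept)
        summary.to_csv(out / "vn_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        outputs["vn_summary"] = out / "vn_summary.tsv"
        for vn in kept:
            export_vn(vn, out / "vns")
            prof = expression_profiles(vn, nm_f)
            ppath = out / "vns" / f"vn_{vn.seed}_profiles.tsv"
            prof.to_csv(ppath, sep="\t", index=False, float_format="%.6g")
    except Exception as err:
        raise RuntimeError(f"[vicinity] {err}") from err
    manifest["stages"][name] = {
        "seeds_requested": len(seed_genes),
        "seeds_not_in_universe": skipped,
        "n_vns": len(vns),
        "n_vns_retained": len(kept),
    }

    manifest["outputs"] = {k: _sha256(p) for k, p in sorted(outputs.items())}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
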