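"""End-to-end orchestration: expression -> DE -> triple network -> LCLMN ->
topology + RWR -> co-expression modules, with a reproducible JSON report.

Every stage persists its outputs under the configured output directory and
contributes its counts and parameters to the run report, so the report alone
documents the run (all thresholds and seeds included).  Reruns with an
identical configuration produce byte-identical reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import coexpression as coex
from . import diffexpr, io, topology, triple_network
from .datatypes import LNCRNA, MRNA
from .rwr import RWRConfig, rwr_permutation_p
from .probe_annotation import collapse_to_transcripts, filter_hits


@dataclass
class PipelineConfig:
    """Paths and thresholds of a full run.

    Expression values must be transcript-level unless ``probe_hits_path`` is
    given, in which case the matrix is probe-level and the annotation stage
    runs first.
    """

    expression_path: str
    design_path: str
    classes_path: str | None
    lnc_interactions_path: str
    mrna_interactions_path: str
    seeds_path: str
    out_dir: str
    probe_hits_path: str | None = None
    de_alpha: float = 0.01
    de_n_perm: int = 1000
    pair_alpha: float = 0.01
    m_universe: int | None = None
    k: int = 10
    r_min: float = 0.6
    p_max: float = 0.05
    restart_prob: float = 0.5
    rwr_tol: float = 1e-10
    rwr_n_perm: int = 5000
    rwr_sig_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "expression_path",
            "design_path",
            "lnc_interactions_path",
            "mrna_interactions_path",
            "seeds_path",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.classes_path and not Path(self.classes_path).exists():
            raise FileNotFoundError(f"classes_path: {self.classes_path}")
        if self.probe_hits_path and not Path(self.probe_hits_path).exists():
            raise FileNotFoundError(f"probe_hits_path: {self.probe_hits_path}")
        for name, lo, hi in (
            ("de_alpha", 0, 1),
            ("pair_alpha", 0, 1),
            ("p_max", 0, 1),
            ("rwr_sig_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}], got {v}")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return (and persist) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # ---- load inputs (+ optional probe annotation) ----
    def _load():
        matrix = io.read_expression(
            config.expression_path, config.design_path, config.classes_path
        )
        if config.probe_hits_path:
            hits = io.read_table(config.probe_hits_path)
            annotation = filter_hits(hits)
            matrix = collapse_to_transcripts(matrix, annotation)
            report["annotate"] = {
                "n_probes_kept": len(annotation.mapping),
                "n_transcripts_kept": len(annotation.transcripts_kept),
            }
        lnc_mi = io.read_interactions(config.lnc_interactions_path, LNCRNA)
        mrna_mi = io.read_interactions(config.mrna_interactions_path, MRNA)
        seeds = io.read_id_list(config.seeds_path)
        return matrix, lnc_mi, mrna_mi, seeds

    matrix, lnc_mi, mrna_mi, seeds = stage("load")(_load)

    # ---- differential expression ----
    def _de():
        result = diffexpr.permutation_adjusted_p(
            matrix, n_perm=config.de_n_perm, seed=config.seed
        )
        de_lnc, de_mrna = diffexpr.select_de(result, alpha=config.de_alpha)
        io.write_table(
            result.table.rename_axis("id").reset_index(), out / "diffexpr.tsv"
        )
        io.write_id_list(de_lnc, out / "de_lncrna.txt")
        io.write_id_list(de_mrna, out / "de_mrna.txt")
        report["diffexpr"] = {
            "s0": result.s0,
            "n_perm": result.n_perm,
            "n_de_lnc": len(de_lnc),
            "n_de_mrna": len(de_mrna),
        }
        return de_lnc, de_mrna

    de_lnc, de_mrna = stage("diffexpr")(_de)

    # ---- triple network and LCLMN ----
    def _network():
        global_net = triple_network.build_global_network(lnc_mi, mrna_mi)
        de_net = triple_network.extract_de_subnetwork(global_net, de_lnc, de_mrna)
        pairs = triple_network.score_cerna_pairs(
            de_net, m_universe=config.m_universe, count_network=global_net
        )
        lclmn = triple_network.build_lclmn(pairs, alpha=config.pair_alpha)
        io.write_table(triple_network.pairs_to_frame(pairs), out / "cerna_pairs.tsv")
        io.write_graph(lclmn, out / "lclmn.graphml", "graphml")
        io.write_graph(lclmn, out / "lclmn.sif", "sif")
        report["network"] = {
            "global": global_net.summary(),
            "de": de_net.summary(),
            "n_pairs_scored": len(pairs),
            "lclmn": {
                "n_lnc": lclmn.graph["n_lnc"],
                "n_mrna": lclmn.graph["n_mrna"],
                "n_edges": lclmn.graph["n_edges"],
            },
        }
        return global_net, lclmn

    global_net, lclmn = stage("network")(_network)
    if lclmn.number_of_edges() == 0:
        report["topology"] = {"top_overlap_lnc": []}
        report["rwr"] = {"significant_lnc": []}
        report["coexpression"] = {"n_pairs_retained": 0, "modules": {}}
        _write_report(report, out)
        return report

    # ---- topology ----
    def _topology():
        table = topology.compute_centralities(lclmn)
        overlap = topology.top_k_overlap(table, k=config.k, restrict_class=LNCRNA)
        io.write_table(table.rename_axis("node").reset_index(), out / "centrality.tsv")
        io.write_id_list(overlap, out / "top_overlap_lnc.txt")
        report["topology"] = {"k": config.k, "top_overlap_lnc": sorted(overlap)}
        return overlap

    overlap = stage("topology")(_topology)

    # ---- random walk with restart ----
    def _rwr():
        cfg = RWRConfig(
            seed_genes=seeds,
            restart_prob=config.restart_prob,
            tol=config.rwr_tol,
            n_perm=config.rwr_n_perm,
            rng_seed=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # absent seeds already in report
            result = rwr_permutation_p(lclmn, cfg)
        io.write_table(
            result.candidates.rename_axis("node").reset_index(), out / "rwr.tsv"
        )
        sig = sorted(
            result.candidates.index[
                result.candidates["perm_p"] < config.rwr_sig_alpha
            ]
        )
        report["rwr"] = {
            "restart_prob": config.restart_prob,
            "n_perm": config.rwr_n_perm,
            "n_seeds_in_network": int(
                len(set(seeds) & set(result.scores.index))
            ),
            "significant_lnc": sig,
        }
        return result

    stage("rwr")(_rwr)

    # ---- co-expression and ceRNA modules ----
    def _coexpr():
        pairs = coex.coexpressed_pairs(
            lclmn, matrix, r_min=config.r_min, p_max=config.p_max
        )
        io.write_table(coex.pairs_to_frame(pairs), out / "coexpressed_pairs.tsv")
        modules = {}
        for lnc in sorted({cp.lnc_id for cp in pairs}):
            module = coex.extract_module(lnc, pairs, global_net)
            io.write_graph(
                module.to_graph(), out / f"module_{lnc}.graphml", "graphml"
            )
            modules[lnc] = {
                "n_mrna": len(module.mrna_ids),
                "n_mirna": len(module.mirna_ids),
            }
        report["coexpression"] = {
            "r_min": config.r_min,
            "p_max": config.p_max,
            "n_pairs_retained": len(pairs),
            "modules": modules,
        }

    stage("coexpression")(_coexpr)

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
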