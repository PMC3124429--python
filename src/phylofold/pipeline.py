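"""End-to-end orchestration of the evolution and stability analyses.

``run_evolution`` goes alignment -> curation -> conservation annotation ->
JTT distances -> NJ (+ bootstrap) -> outgroup rerooting -> tracked-site tip
annotation -> RF against the species tree -> duplication-loss reconciliation
(with a D/L root scan) -> ancestral reconstruction at the tracked columns.
``run_stability`` fits every provided equilibrium curve and kinetic trace
and tabulates the wild-type/variant comparison (ddG, Cm shift, rates).

Every stage writes its intermediate to the output directory and the bundle
is summarized as JSON; all randomness is controlled by the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .asr import discretize_gamma, joint_asr, marginal_asr
from .conservation import annotate_alignment, write_annotation_tsv
from .family_io import (
    Alignment,
    read_alignment,
    read_species_map,
    map_position,
    select_species_representatives,
)
from .foldstab import (
    delta_delta_g,
    fit_equilibrium,
    fit_kinetics,
    read_denaturation_tsv,
    read_trace_tsv,
)
from .phylo_build import (
    annotate_tips_with_site_states,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    reroot,
)
from .reconcile import DEFAULT_COSTS, infer_root_by_dl, lca_reconcile, root_by_dl
from .substmodel import jtt_model
from .tree_compare import prune_to_unique, rf_detail
from .treeutils import PhyloTree


@dataclass
class PipelineConfig:
    alignment: str | None = None
    species_tree: str | None = None
    species_map: str | None = None
    outgroup: str | None = None
    reference_id: str | None = None
    tracked_positions: list[int] = field(default_factory=list)  # mature numbering
    alpha: float = 1.0
    gamma_categories: int = 4
    bootstrap_replicates: int = 100
    dl_costs: tuple[float, float] = DEFAULT_COSTS
    curves: dict = field(default_factory=dict)  # name -> tsv path
    traces: dict = field(default_factory=dict)
    reference_curve: str | None = None
    variant_curve: str | None = None
    outdir: str = "phylofold_out"
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_evolution(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"seed": config.seed, "version": __version__}}

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, e) from e

        return wrap

    smap = read_species_map(config.species_map) if config.species_map else None
    aln = stage("read_alignment")(
        read_alignment, config.alignment, species_map=smap
    )
    aln = stage("curate")(select_species_representatives, aln)
    report["n_sequences"] = len(aln)

    annotations = stage("conserve")(annotate_alignment, aln)
    write_annotation_tsv(annotations, out / "conservation.tsv")

    columns = []
    if config.reference_id and config.tracked_positions:
        columns = [
            stage("map_position")(map_position, aln, config.reference_id, p)
            for p in config.tracked_positions
        ]
    report["tracked_columns"] = columns

    model = jtt_model()
    dm = stage("distances")(distance_matrix, aln, model)
    dm.to_tsv(out / "distances.tsv")
    if config.bootstrap_replicates > 0:
        tree = stage("bootstrap")(
            bootstrap_support, aln, model,
            replicates=config.bootstrap_replicates, seed=config.seed,
        )
    else:
        tree = stage("nj")(nj_tree, dm)
    if config.outgroup:
        tree = stage("reroot")(reroot, tree, config.outgroup)
    tree.write(out / "gene_tree.nwk")

    if columns:
        annotated = stage("annotate_tips")(
            annotate_tips_with_site_states, tree, aln, columns
        )
        annotated.write(out / "gene_tree_annotated.nwk")

    if config.species_tree:
        species = PhyloTree.read(config.species_tree, rooted=True)
        mapping = {r.id: r.species for r in aln.records}
        pruned = stage("prune")(prune_to_unique, tree, mapping)
        report["rf_vs_species_tree"] = stage("rfdist")(
            rf_detail, pruned, species, mapping
        )
        gene_for_rec = tree
        if not (tree.rooted and tree.is_binary()):
            gene_for_rec, _ = stage("dl_root")(
                root_by_dl, nj_tree(dm), species, mapping, config.dl_costs
            )
        rec = stage("reconcile")(
            lca_reconcile, gene_for_rec, species, mapping, config.dl_costs
        )
        report["reconciliation"] = rec.to_dict()
        scan = stage("dl_root_scan")(
            infer_root_by_dl, nj_tree(dm), species, mapping, config.dl_costs
        )
        report["dl_root_scan_best"] = scan[0]

    if columns:
        gamma = discretize_gamma(config.alpha, config.gamma_categories)
        marg = stage("asr")(marginal_asr, tree, aln, model, gamma)
        joint = stage("asr_joint")(joint_asr, tree, aln, model, gamma)
        tracked = {}
        root_name = marg.node_names[0]
        for pos, col in zip(config.tracked_positions, columns):
            state, prob = marg.marginal_mode(root_name, col)
            tracked[str(pos)] = {
                "column": col,
                "root_marginal_state": state,
                "root_marginal_probability": prob,
                "root_joint_state": joint.joint_states[root_name][col - 1],
            }
        report["ancestral_tracked_sites"] = tracked
        report["joint_log_likelihood"] = joint.joint_log_likelihood

    (out / "evolution_report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n"
    )
    return report


def run_stability(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"seed": config.seed, "version": __version__}}

    eq_fits = {}
    for name, path in config.curves.items():
        try:
            curve = read_denaturation_tsv(path)
        except OSError as e:
            raise StageError(f"read_curve:{name}", e) from e
        fit = fit_equilibrium(curve)
        eq_fits[name] = fit
        report.setdefault("equilibrium", {})[name] = fit.to_dict()

    for name, path in config.traces.items():
        try:
            trace = read_trace_tsv(path)
        except OSError as e:
            raise StageError(f"read_trace:{name}", e) from e
        fit = fit_kinetics(trace)
        report.setdefault("kinetics", {})[name] = fit.to_dict()

    ref, var = config.reference_curve, config.variant_curve
    if ref in eq_fits and var in eq_fits:
        report["stability_comparison"] = delta_delta_g(eq_fits[ref], eq_fits[var])

    (out / "stability_report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n"
    )
    return report
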