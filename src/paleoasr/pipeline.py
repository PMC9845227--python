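"""Orchestration of the full study design.

The study grid crosses two coding approaches (preferred, alternate)
with three inference methods (maximum parsimony, maximum likelihood,
Bayesian) and two branch-length modes (timescaled from stratigraphy,
unit lengths).  Parsimony ignores branch lengths, so it is computed
once per coding and reported in both branch-length cells with a note.
Clade-level summaries are read off at the MRCA of each named clade's
defining taxa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import AsrResult, McmcSettings, bayes_asr, fit_mk, marginal_asr_ml, sankoff_parsimony
from .coding import CharacterCoding, SpecimenEvidence, code_alternate, code_preferred, read_evidence
from .timescale import StratRange, read_strat_ranges, timescale_tree, unit_branch_lengths
from .trees import (
    CladeDefinition,
    GraftConflictError,
    Tree,
    graft,
    parse_newick,
    read_newick_file,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    """Everything one study run needs; loadable from a YAML file."""

    backbone: Union[str, Path]
    sources: list[tuple[Union[str, Path], str]]  # (tree path, landmark)
    ranges: Union[str, Path]
    evidence: Union[str, Path]
    clades: dict[str, list[str]]
    mbl: float = 1.0
    tip_age_policy: str = "fad"
    min_ribs: int = 5
    parameterization: str = "ER"
    root_prior: str = "flat"
    mcmc_iterations: int = 100_000
    burn_in_fraction: float = 0.2
    thin: int = 50
    seed: int = 0
    outdir: Optional[Union[str, Path]] = None

    def clade_definitions(self) -> list[CladeDefinition]:
        return [CladeDefinition(name, frozenset(taxa)) for name, taxa in self.clades.items()]


def load_config(path) -> StudyConfig:
    """Read a YAML study config; relative paths resolve against the file."""
    path = Path(path)
    base = path.parent
    raw = yaml.safe_load(path.read_text())
    mcmc = raw.get("mcmc", {})
    return StudyConfig(
        backbone=base / raw["backbone"],
        sources=[(base / s["tree"], s["landmark"]) for s in raw.get("sources", [])],
        ranges=base / raw["ranges"],
        evidence=base / raw["evidence"],
        clades=raw["clades"],
        mbl=float(raw.get("mbl", 1.0)),
        tip_age_policy=raw.get("tip_age_policy", "fad"),
        min_ribs=int(raw.get("min_ribs", 5)),
        parameterization=raw.get("parameterization", "ER"),
        root_prior=raw.get("root_prior", "flat"),
        mcmc_iterations=int(mcmc.get("iterations", 100_000)),
        burn_in_fraction=float(mcmc.get("burn_in_fraction", 0.2)),
        thin=int(mcmc.get("thin", 50)),
        seed=int(raw.get("seed", 0)),
        outdir=raw.get("outdir"),
    )


# ---------------------------------------------------------------------------
# Supertree assembly
# ---------------------------------------------------------------------------

def assemble_supertree_from_parts(
    backbone: Union[str, Tree],
    sources: Sequence[tuple[Union[str, Tree], str]],
) -> Tree:
    """Sequentially graft source trees onto the backbone.

    Taxa shared with the *original* backbone act as landmarks (extra
    shared taxa are pruned from the grafted piece with a warning); a
    source that re-introduces a taxon added by an earlier source is a
    hard conflict and aborts with the source named.
    """
    tree = parse_newick(backbone) if isinstance(backbone, str) else backbone.copy()
    original = set(tree.leaf_labels())
    added: set[str] = set()
    for i, (src, landmark) in enumerate(sources, 1):
        source = parse_newick(src) if isinstance(src, str) else src
        src_taxa = set(source.leaf_labels())
        clash = (src_taxa & added) - original
        if clash:
            raise GraftConflictError(
                f"source {i} re-introduces taxa already grafted: {sorted(clash)}"
            )
        before = set(tree.leaf_labels())
        tree = graft(tree, source, landmark)
        added |= set(tree.leaf_labels()) - before
    return tree


def assemble_supertree(config: StudyConfig) -> Tree:
    backbone = read_newick_file(config.backbone)
    sources = [(read_newick_file(p), lm) for p, lm in config.sources]
    return assemble_supertree_from_parts(backbone, sources)


# ---------------------------------------------------------------------------
# Clade summaries
# ---------------------------------------------------------------------------

def extract_clade_probability(
    result: AsrResult,
    tree: Tree,
    clade: CladeDefinition,
    tie_tol: float = 1e-6,
) -> dict:
    """Ancestral-state summary at a named clade's MRCA node.

    For ML/MB: the probability vector and argmax state (ties within
    ``tie_tol`` reported jointly, e.g. "0/1").  For MP: the MPR set.
    """
    node = tree.mrca(clade.defining_taxa)
    value = result.node_states[node.id]
    if isinstance(value, frozenset):
        best = "/".join(str(s) for s in sorted(value))
        return {"clade": clade.name, "node": node.id, "mpr_set": sorted(value), "best": best}
    probs = [float(p) for p in value]
    top = max(probs)
    best_states = [s for s, p in enumerate(probs) if p >= top - tie_tol]
    return {
        "clade": clade.name,
        "node": node.id,
        "probabilities": probs,
        "best": "/".join(str(s) for s in best_states),
    }


# ---------------------------------------------------------------------------
# The grid
# ---------------------------------------------------------------------------

@dataclass
class GridReport:
    """Rows of (coding, method, branch mode, clade, summary) + provenance."""

    rows: list[dict]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {k: r[k] for k in ("coding", "method", "branch_mode", "clade", "best", "status")}
            if "probabilities" in r:
                for s, p in enumerate(r["probabilities"]):
                    rec[f"p_state{s}"] = round(p, 2)  # printed at study precision
            if "mpr_set" in r:
                rec["mpr_set"] = "/".join(map(str, r["mpr_set"]))
            rec["note"] = r.get("note", "")
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "rows": self.rows},
            indent=2,
            sort_keys=True,
        )

    def cell(self, coding: str, method: str, branch_mode: str, clade: str) -> dict:
        for r in self.rows:
            if (r["coding"], r["method"], r["branch_mode"], r["clade"]) == (
                coding, method, branch_mode, clade,
            ):
                return r
        raise KeyError((coding, method, branch_mode, clade))


def run_grid(
    config: StudyConfig,
    tree: Optional[Tree] = None,
    evidence: Optional[list[SpecimenEvidence]] = None,
    ranges: Optional[dict[str, StratRange]] = None,
) -> GridReport:
    """Run the full 2 codings × 3 methods × 2 branch-length grid.

    Inputs may be passed in-memory (tree/evidence/ranges) or read from
    the paths in ``config``.  A failed cell is recorded as failed; the
    other cells are still produced.  Identical config + seed gives a
    byte-identical report.
    """
    if tree is None:
        tree = assemble_supertree(config)
    if evidence is None:
        evidence = read_evidence(config.evidence)
    if ranges is None:
        ranges = read_strat_ranges(config.ranges)

    clades = config.clade_definitions()
    for cd in clades:
        missing = cd.defining_taxa - set(tree.leaf_labels())
        if missing:
            raise PipelineError(f"clade {cd.name}: taxa not in supertree: {sorted(missing)}")

    codings = {
        "preferred": code_preferred(evidence),
        "alternate": code_alternate(evidence, min_ribs=config.min_ribs),
    }
    modes = {
        "timescaled": timescale_tree(tree, ranges, mbl=config.mbl,
                                     tip_age_policy=config.tip_age_policy),
        "unit": unit_branch_lengths(tree),
    }

    rows: list[dict] = []
    mb_cell_index = 0
    for coding_name, coding in codings.items():
        # parsimony once per coding; identical in both branch-length cells
        try:
            mp = sankoff_parsimony(modes["unit"], coding)
            mp_rows = [extract_clade_probability(mp, modes["unit"], cd) for cd in clades]
            mp_err = None
        except Exception as exc:  # recorded, not raised
            mp_rows, mp_err = None, str(exc)
        for mode_name in modes:
            for i, cd in enumerate(clades):
                if mp_err is not None:
                    rows.append({"coding": coding_name, "method": "MP",
                                 "branch_mode": mode_name, "clade": cd.name,
                                 "best": "", "status": f"failed: {mp_err}"})
                else:
                    r = dict(mp_rows[i])
                    r.update(coding=coding_name, method="MP", branch_mode=mode_name,
                             status="ok",
                             note="branch-length invariant (computed once per coding)")
                    rows.append(r)

        for mode_name, mode_tree in modes.items():
            try:
                model, loglik, converged = fit_mk(
                    mode_tree, coding,
                    parameterization=config.parameterization,
                    root_prior=config.root_prior,
                )
                ml = marginal_asr_ml(mode_tree, coding, model)
                for cd in clades:
                    r = extract_clade_probability(ml, mode_tree, cd)
                    r.update(coding=coding_name, method="ML", branch_mode=mode_name,
                             status="ok" if converged else "ok (optimizer not converged)",
                             rate=float(model.rates[0]), log_likelihood=loglik)
                    rows.append(r)
            except Exception as exc:
                for cd in clades:
                    rows.append({"coding": coding_name, "method": "ML",
                                 "branch_mode": mode_name, "clade": cd.name,
                                 "best": "", "status": f"failed: {exc}"})

            try:
                mcmc = McmcSettings(
                    iterations=config.mcmc_iterations,
                    burn_in_fraction=config.burn_in_fraction,
                    thin=config.thin,
                    seed=(config.seed + mb_cell_index) % (2**31),
                )
                mb = bayes_asr(mode_tree, coding, mcmc, root_prior=config.root_prior)
                for cd in clades:
                    r = extract_clade_probability(mb, mode_tree, cd)
                    r.update(coding=coding_name, method="MB", branch_mode=mode_name,
                             status="ok",
                             ess=mb.diagnostics["ess_rate"],
                             acceptance_rate=mb.diagnostics["acceptance_rate"],
                             seed=mcmc.seed)
                    rows.append(r)
            except Exception as exc:
                for cd in clades:
                    rows.append({"coding": coding_name, "method": "MB",
                                 "branch_mode": mode_name, "clade": cd.name,
                                 "best": "", "status": f"failed: {exc}"})
            mb_cell_index += 1

    provenance = {
        "package": "paleo-asr",
        "version": __version__,
        "seed": config.seed,
        "mbl": config.mbl,
        "tip_age_policy": config.tip_age_policy,
        "min_ribs": config.min_ribs,
        "parameterization": config.parameterization,
        "root_prior": config.root_prior,
        "mcmc": {"iterations": config.mcmc_iterations,
                 "burn_in_fraction": config.burn_in_fraction, "thin": config.thin},
        "n_tips": tree.n_tips,
        "clades": {cd.name: sorted(cd.defining_taxa) for cd in clades},
    }
    report = GridReport(rows=rows, provenance=provenance)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "grid_report.tsv").write_text(report.to_tsv())
        (outdir / "grid_report.json").write_text(report.to_json())
    return report
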