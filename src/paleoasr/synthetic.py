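"""Synthetic trees, characters, ranges and specimen evidence.

Everything the analysis consumes can be generated here, with the
statistical structure the inference assumes: a birth–death tree with
true node ages, a 3-state character evolving under an ER Mk process, a
stratigraphic layer whose first/last appearances bracket the true tip
ages, and an observation layer in which uncinate scars are detected
only probabilistically on preserved ribs.

`make_study_fixture` packages a fixed, fully deterministic ~40-tip
archosaur-shaped dataset that mirrors the shape of the real study: one
outgroup coded absent by expert override, 22 taxa with positive
evidence (ossified processes confined to a nested pennaraptoran-like
clade), nine taxa with ≥5 scar-free ribs (codeable absent under the
alternate approach), the rest uncertain, plus four nested named clades.
The fixture is synthetic throughout — taxon names, topology, ages and
rib counts are invented, not measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .coding import SpecimenEvidence, write_evidence
from .timescale import StratRange, write_strat_ranges
from .trees import Node, Tree, write_newick, write_newick_file
from .asr import MkModel


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    """Study-shaped simulation settings.

    Defaults emulate the real data's scale: a ~40-taxon archosaur-grade
    tree spanning a couple hundred Myr, a slow 3-state character
    (q = 0.005 events/Myr per state pair), modest per-taxon rib samples
    (Poisson mean 4) and imperfect scar detection (40% per rib).
    """

    n_tips: int = 40
    birth_rate: float = 0.06   # per Myr
    death_rate: float = 0.03   # per Myr
    q: float = 0.005           # Mk rate, events/Myr per ordered state pair
    root_state: int = 1
    rib_count_mean: float = 4.0
    scar_detection_prob: float = 0.4    # per preserved rib, states 1 and 2
    process_preservation_prob: float = 0.5  # ossified process fossilizes, state 2
    false_positive_prob: float = 0.0
    range_offset: float = 5.0  # max Myr between true tip age and FAD/LAD
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise SimulationError("n_tips must be >= 2")
        if min(self.birth_rate, self.q) < 0 or self.death_rate < 0:
            raise SimulationError("rates must be >= 0")
        for p in (self.scar_detection_prob, self.process_preservation_prob,
                  self.false_positive_prob):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Birth-death tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    seed: int = 0,
    max_retries: int = 100,
) -> Tree:
    """Forward birth–death simulation conditioned on ``n_tips`` extant tips.

    Simulation starts from a single lineage; when the extant count first
    reaches ``n_tips`` the tree is extended by the waiting time to the
    next event at that count (so the expected root age of a Yule tree
    is Σ_{i=2..n} 1/(λ i)).  Extinct lineages are pruned.  Lineages that
    die out before reaching ``n_tips`` trigger a bounded resample.
    Reproducible under ``seed``: identical seeds give identical Newick.
    """
    if n_tips < 2:
        raise SimulationError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise SimulationError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        root = Node()
        active: list[tuple[Node, float]] = [(root, 0.0)]  # (node, birth time)
        t = 0.0
        ok = False
        while True:
            n = len(active)
            if n == 0:
                break
            total = n * (birth_rate + death_rate)
            wait = rng.exponential(1.0 / total)
            if n == n_tips:
                t += wait  # extend to just before the next event, then stop
                ok = True
                break
            t += wait
            idx = int(rng.integers(n))
            node, born = active.pop(idx)
            if rng.uniform() < birth_rate / (birth_rate + death_rate):
                node.length = t - born if node is not root else None
                c1, c2 = Node(), Node()
                node.add_child(c1)
                node.add_child(c2)
                active.append((c1, t))
                active.append((c2, t))
            else:
                node.length = t - born if node is not root else None
                node.label = "__extinct__"
        if not ok:
            continue
        for node, born in active:
            node.length = t - born if node is not root else None

        pruned = _prune_extinct(root)
        if pruned is None:
            continue
        tips = [n for n in pruned.postorder() if n.is_leaf]
        if len(tips) != n_tips:
            continue
        for i, tip in enumerate(tips):
            tip.label = f"t{i + 1:03d}"
        pruned.length = None
        tree = Tree(pruned)
        _set_ages_from_lengths(tree)
        tree.branch_mode = "timescaled"
        return tree
    raise SimulationError(f"failed to reach {n_tips} extant tips in {max_retries} tries")


def _prune_extinct(root: Node) -> Optional[Node]:
    def walk(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return None if node.label == "__extinct__" else node
        kept = [k for k in (walk(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            return only
        node.children = kept
        for k in kept:
            k.parent = node
        return node

    out = walk(root)
    if out is not None:
        out.parent = None
    return out


def _set_ages_from_lengths(tree: Tree) -> None:
    """Node ages in Ma assuming all extant tips end at the present (0 Ma)."""
    depth: dict[int, float] = {tree.root.id: 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[node.id] = depth[node.parent.id] + (node.length or 0.0)
    total = max(depth[n.id] for n in tree.leaves())
    for node in tree.postorder():
        node.age = total - depth[node.id]


def yule_expected_root_age(n_tips: int, birth_rate: float) -> float:
    """Closed-form expected root age of a Yule tree under the stopping
    convention of :func:`simulate_tree`: Σ_{i=2..n} 1/(λ i)."""
    return sum(1.0 / (birth_rate * i) for i in range(2, n_tips + 1))


# ---------------------------------------------------------------------------
# Character and observation layers
# ---------------------------------------------------------------------------

def simulate_mk_character(
    tree: Tree,
    q: float,
    root_state: int = 1,
    seed: int = 0,
    k: int = 3,
) -> dict[str, int]:
    """Evolve a k-state ER character down the tree; returns tip → state.

    Each child's state is drawn from the ER transition row
    exp(Qt)[parent_state] for its branch; q = 0 freezes the character.
    """
    if not 0 <= root_state < k:
        raise SimulationError(f"root_state must be in [0, {k})")
    rng = np.random.default_rng(seed)
    model = MkModel(k, "ER", np.array([max(q, 1e-300)]))
    states: dict[int, int] = {tree.root.id: root_state}
    tips: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is not None:
            if node.length is None:
                raise SimulationError("branch lengths must be set")
            if q == 0:
                s = states[node.parent.id]
            else:
                row = model.transition_matrix(node.length)[states[node.parent.id]]
                s = int(rng.choice(k, p=row / row.sum()))
            states[node.id] = s
        if node.is_leaf:
            tips[node.label] = states[node.id]
    return tips


def simulate_strat_ranges(
    tree: Tree,
    max_offset: float = 5.0,
    seed: int = 0,
) -> dict[str, StratRange]:
    """Ranges bracketing each tip's true age: FAD = age + U(0, offset),
    LAD = age − U(0, offset) clipped at 0.  Guarantees FAD ≥ LAD ≥ 0."""
    rng = np.random.default_rng(seed)
    out = {}
    for tip in tree.leaves():
        if tip.age is None:
            raise SimulationError("tree has no node ages; timescale it first")
        fad = tip.age + rng.uniform(0, max_offset)
        lad = max(0.0, tip.age - rng.uniform(0, max_offset))
        out[tip.label] = StratRange(tip.label, float(fad), float(lad))
    return out


def simulate_evidence(
    tip_states: dict[str, int],
    spec: SimulationSpec,
) -> list[SpecimenEvidence]:
    """Observation layer: preserved ribs, probabilistic scar detection.

    Rib counts are Poisson(``rib_count_mean``).  For state-1/2 taxa each
    rib independently shows a scar with ``scar_detection_prob``; state-2
    taxa additionally preserve an ossified process with
    ``process_preservation_prob``.  State-0 taxa yield scars only at
    ``false_positive_prob`` (0 by default).
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for taxon in sorted(tip_states):
        state = tip_states[taxon]
        n_ribs = int(rng.poisson(spec.rib_count_mean))
        p_scar = spec.scar_detection_prob if state in (1, 2) else spec.false_positive_prob
        n_scar = int(rng.binomial(n_ribs, p_scar)) if n_ribs else 0
        process = "none"
        if state == 2 and rng.uniform() < spec.process_preservation_prob:
            process = "ossified"
        rows.append(SpecimenEvidence(taxon, n_ribs, n_scar, process))
    return rows


# ---------------------------------------------------------------------------
# The packaged study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """Deterministic archosaur-shaped dataset mirroring the study's scale.

    Synthetic throughout: names, topology, ranges and evidence are
    constructed, not observed.
    """

    backbone_newick: str
    sources: list[tuple[str, str]]           # (newick, landmark)
    supertree_newick: str
    ranges: dict[str, StratRange]
    evidence: list[SpecimenEvidence]
    clades: dict[str, list[str]]

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "backbone": outdir / "backbone.nwk",
            "supertree": outdir / "supertree.nwk",
            "ranges": outdir / "ranges.tsv",
            "evidence": outdir / "evidence.tsv",
            "clades": outdir / "clades.yaml",
            "config": outdir / "config.yaml",
        }
        paths["backbone"].write_text(self.backbone_newick + "\n")
        paths["supertree"].write_text(self.supertree_newick + "\n")
        source_files = []
        for i, (nwk, landmark) in enumerate(self.sources, 1):
            p = outdir / f"source{i:02d}.nwk"
            p.write_text(nwk + "\n")
            source_files.append({"tree": p.name, "landmark": landmark})
        write_strat_ranges(self.ranges, paths["ranges"])
        write_evidence(self.evidence, paths["evidence"])
        paths["clades"].write_text(yaml.safe_dump({"clades": self.clades}, sort_keys=True))
        config = {
            "backbone": "backbone.nwk",
            "sources": source_files,
            "ranges": "ranges.tsv",
            "evidence": "evidence.tsv",
            "clades": self.clades,
            "mbl": 1.0,
            "tip_age_policy": "fad",
            "min_ribs": 5,
            "mcmc": {"iterations": 100000, "burn_in_fraction": 0.2, "thin": 50},
            "seed": 20230,
        }
        paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
        return paths


_GROUPS = {
    # group → (source newick, landmark)
    "pseudo": ("(pseudo01,(pseudo02,((pseudo03,(pseudo04,pseudo05)),"
               "(pseudo06,(pseudo07,pseudo08)))));", "pseudo01"),
    "ornitho": ("((ornitho01,(ornitho02,ornitho03)),(ornitho04,(ornitho05,ornitho06)));",
                "ornitho01"),
    "sauro": ("(sauro01,((sauro02,sauro03),(sauro04,(sauro05,sauro06))));", "sauro01"),
    "thero": ("(thero01,((thero02,thero03),(thero04,(thero05,(thero06,thero07)))));",
              "thero01"),
    "manira": ("(manira01,(manira02,(manira03,manira04)));", "manira01"),
    "penna": ("(penna01,((penna02,(penna03,penna04)),(penna05,(penna06,"
              "(penna07,penna08)))));", "penna01"),
}

_BACKBONE = "(OUT01,(pseudo01,(ornitho01,(sauro01,(thero01,(manira01,penna01))))));"

# (group, first FAD in Ma, step between successive taxa, range duration)
_AGES = {
    "pseudo": (248.0, 5.0, 4.0),
    "ornitho": (200.0, 12.0, 5.0),
    "sauro": (210.0, 14.0, 6.0),
    "thero": (230.0, 16.0, 5.0),
    "manira": (125.0, 10.0, 4.0),
    "penna": (125.0, 7.0, 3.0),
}

# evidence category per taxon: (n_ribs, n_scars, process)
_SCAR = {"pseudo": (1, 2), "ornitho": (1, 2, 3), "sauro": (1, 2, 3),
         "thero": (1, 2, 3, 4), "manira": (1, 2)}
_ABSENT = {"pseudo": (3, 4, 5, 6), "ornitho": (4, 5), "sauro": (4, 5)}


def make_study_fixture() -> StudyFixture:
    """Build the fixed study-shaped dataset (byte-identical every call)."""
    from .pipeline import assemble_supertree_from_parts  # local: avoid cycle

    backbone = _BACKBONE
    sources = [(_GROUPS[g][0], _GROUPS[g][1]) for g in _GROUPS]
    supertree = assemble_supertree_from_parts(backbone, sources)
    supertree_newick = write_newick(supertree)

    ranges: dict[str, StratRange] = {"OUT01": StratRange("OUT01", 242.0, 236.0)}
    evidence: list[SpecimenEvidence] = [
        # outgroup: 13 well-preserved scar-free ribs, expert-coded absent
        SpecimenEvidence("OUT01", 13, 0, "none", override_state=frozenset({0})),
    ]
    from .trees import parse_newick

    for group, (nwk, _) in _GROUPS.items():
        taxa = sorted(parse_newick(nwk).leaf_labels())
        start, step, dur = _AGES[group]
        scar_idx = set(_SCAR.get(group, ()))
        absent_idx = set(_ABSENT.get(group, ()))
        for i, taxon in enumerate(taxa, 1):
            fad = start - step * (i - 1)
            ranges[taxon] = StratRange(taxon, fad, max(0.0, fad - dur))
            if group == "penna":
                # ossified processes preserved throughout the nested clade
                evidence.append(SpecimenEvidence(taxon, 3 + (i % 3), i % 2, "ossified"))
            elif i in scar_idx:
                evidence.append(SpecimenEvidence(taxon, 3 + (i % 4), 1 + (i % 2), "none"))
            elif i in absent_idx:
                evidence.append(SpecimenEvidence(taxon, 5 + i, 0, "none"))
            else:
                evidence.append(SpecimenEvidence(taxon, i % 4, 0, "none"))

    clades = {
        "Archosauria": ["pseudo01", "penna01"],
        "Dinosauria": ["ornitho01", "penna01"],
        "Maniraptoriformes": ["manira01", "penna01"],
        "Pennaraptora": ["penna01", "penna08"],
    }
    return StudyFixture(
        backbone_newick=backbone,
        sources=sources,
        supertree_newick=supertree_newick,
        ranges=ranges,
        evidence=evidence,
        clades=clades,
    )
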