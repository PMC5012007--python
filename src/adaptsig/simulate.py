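"""Synthetic experiment generator.

Emulates the statistical structure of a label-free (phospho-)proteomic
drug-adaptation study: several melanoma-like cell lines, each profiled as
drug-naive *parental*, short-term drug-exposed *persistent*, and chronically
adapted *resistant* populations, with replicate log-normal intensity noise
and intensity-dependent missingness (left-censoring flavour).

Three effect programs are planted on disjoint protein sets:

``shared_up``
    Upregulated in *both* the persistent and the resistant state — the
    analog of the signaling alterations shared between early and late
    adaptation (JUN-like candidates) that the combined perturbation score
    is designed to recover.
``persistent_down``
    Downregulated only in the persistent state (cell-cycle/translation-like
    growth-arrest program).
``resistant_up``
    Upregulated only in the resistant state (mesenchymal/invasive-like
    program).

Cell lines carry a mechanism label: ``RTK`` lines undergo the mesenchymal
shift and the shared program; ``NRAS`` lines (MAPK-reactivation control)
receive neither by default, mirroring the BRAF-mutant specificity of the
shared response.  Both gates are independently configurable.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneSetCollection, QuantTable, STATES

__all__ = [
    "CellLineSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "make_expression_twin",
]


@dataclass(frozen=True)
class CellLineSpec:
    name: str
    mechanism: str = "RTK"  # "RTK" or "NRAS"
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        if self.mechanism not in ("RTK", "NRAS"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"unknown states {sorted(bad)}")


def _default_lines() -> tuple[CellLineSpec, ...]:
    return (
        CellLineSpec("RTK1", "RTK"),
        CellLineSpec("RTK2", "RTK"),
        CellLineSpec("NRAS1", "NRAS"),
    )


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate_experiment`.

    Defaults describe a realistic small label-free design: 1,000 proteins
    with 1–5 phospho-sites each, three cell lines (two RTK-mechanism, one
    NRAS-mechanism control), n=3 replicates per (line, state) group,
    baseline log2 intensities ~ N(24, 2²), replicate noise σ=0.5 log2
    units, and planted 4-fold (±2 log2) effect programs.
    """

    n_proteins: int = 1000
    sites_per_protein: tuple[int, int] = (1, 5)  # uniform inclusive range
    cell_lines: tuple[CellLineSpec, ...] = field(default_factory=_default_lines)
    replicates: int = 3
    baseline_mean: float = 24.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    # planted programs: (number of proteins, log2 effect size)
    n_shared_up: int = 20
    shared_up_effect: float = 2.0
    n_persistent_down: int = 30
    persistent_down_effect: float = -2.0
    n_resistant_up: int = 30
    resistant_up_effect: float = 2.0
    n_resistant_down: int = 30
    resistant_down_effect: float = -2.0
    # mechanism gating
    shared_in_nras: bool = False
    mesenchymal_in_nras: bool = False
    # missingness: detection probability = logistic((x - midpoint)/scale)
    missing_midpoint: float | None = None  # None disables missingness
    missing_scale: float = 1.0
    n_decoy_sets: int = 10
    expression_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.sites_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("sites_per_protein must be an increasing range >= 1")
        n_planted = (self.n_shared_up + self.n_persistent_down
                     + self.n_resistant_up + self.n_resistant_down)
        if n_planted > self.n_proteins:
            raise ValueError("planted programs exceed protein universe")
        for eff in (self.shared_up_effect, self.persistent_down_effect,
                    self.resistant_up_effect, self.resistant_down_effect):
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        if self.missing_scale <= 0:
            raise ValueError("missing_scale must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = [asdict(cl) | {"states": list(cl.states)} for cl in self.cell_lines]
        d["sites_per_protein"] = list(self.sites_per_protein)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cell_lines" in d:
            d["cell_lines"] = tuple(
                CellLineSpec(c["name"], c.get("mechanism", "RTK"), tuple(c.get("states", STATES)))
                for c in d["cell_lines"]
            )
        if "sites_per_protein" in d:
            d["sites_per_protein"] = tuple(d["sites_per_protein"])
        return cls(**d)


PROGRAMS = ("shared_up", "persistent_down", "resistant_up", "resistant_down")


@dataclass
class GroundTruth:
    """Planted truth: program membership and per-protein effects.

    ``protein_effects`` is indexed by protein_id with one column per
    ``"<cell_line>:<state>"`` group holding the planted log2 effect
    relative to that line's parental group.
    """

    programs: dict[str, tuple[str, ...]]
    protein_effects: pd.DataFrame
    config: SimulationConfig

    def effect(self, protein_id: str, cell_line: str, state: str) -> float:
        return float(self.protein_effects.loc[protein_id, f"{cell_line}:{state}"])

    def to_json(self, path: str | Path) -> None:
        d = {
            "programs": {k: list(v) for k, v in self.programs.items()},
            "protein_effects": {
                "index": list(self.protein_effects.index),
                "columns": list(self.protein_effects.columns),
                "data": self.protein_effects.to_numpy().tolist(),
            },
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(d, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        pe = pd.DataFrame(
            d["protein_effects"]["data"],
            index=d["protein_effects"]["index"],
            columns=d["protein_effects"]["columns"],
        )
        return cls(
            programs={k: tuple(v) for k, v in d["programs"].items()},
            protein_effects=pe,
            config=SimulationConfig.from_dict(d["config"]),
        )


def _detection_prob(x: np.ndarray, midpoint: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - midpoint) / scale))


def _program_effect(cfg: SimulationConfig, program: str, mechanism: str, state: str) -> float:
    """Planted log2 effect contributed by a program in one (mechanism, state)."""
    if state == "parental":
        return 0.0
    if program == "shared_up":
        if mechanism == "NRAS" and not cfg.shared_in_nras:
            return 0.0
        return cfg.shared_up_effect  # both persistent and resistant
    if program == "persistent_down":
        return cfg.persistent_down_effect if state == "persistent" else 0.0
    if program == "resistant_up":
        if mechanism == "NRAS" and not cfg.mesenchymal_in_nras:
            return 0.0
        return cfg.resistant_up_effect if state == "resistant" else 0.0
    if program == "resistant_down":
        if mechanism == "NRAS" and not cfg.mesenchymal_in_nras:
            return 0.0
        return cfg.resistant_down_effect if state == "resistant" else 0.0
    raise ValueError(program)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[QuantTable, GeneSetCollection, GroundTruth]:
    """Generate a phospho-site quantification table with planted programs.

    Returns the site-level :class:`QuantTable` (log2 scale), a
    :class:`GeneSetCollection` containing the planted protein programs,
    size-matched decoy protein sets, and site-level substrate sets (the
    planted "kinase" = the sites of the shared_up proteins, plus decoy
    substrate sets), and the :class:`GroundTruth`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]

    # assign disjoint planted programs
    order = rng.permutation(cfg.n_proteins)
    cursor = 0
    programs: dict[str, tuple[str, ...]] = {}
    for name, n in (
        ("shared_up", cfg.n_shared_up),
        ("persistent_down", cfg.n_persistent_down),
        ("resistant_up", cfg.n_resistant_up),
        ("resistant_down", cfg.n_resistant_down),
    ):
        programs[name] = tuple(sorted(proteins[i] for i in order[cursor : cursor + n]))
        cursor += n
    planted_all = set().union(*(programs[p] for p in PROGRAMS))

    # sites per protein
    lo, hi = cfg.sites_per_protein
    n_sites = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    residues = rng.choice(np.array(["S", "T", "Y"]), size=int(n_sites.sum()), p=[0.6, 0.3, 0.1])
    positions = rng.integers(1, 999, size=int(n_sites.sum()))

    fids: list[str] = []
    f_prot: list[str] = []
    f_site: list[str] = []
    k = 0
    for p, ns in zip(proteins, n_sites):
        used: set[str] = set()
        for _ in range(int(ns)):
            lab = f"{residues[k]}{positions[k]}"
            while lab in used:  # regenerate colliding site labels deterministically
                lab = lab + "b"
            used.add(lab)
            fids.append(f"{p}_{lab}")
            f_prot.append(p)
            f_site.append(lab)
            k += 1
    n_feat = len(fids)

    # sample layout
    groups: list[tuple[str, str]] = []
    for cl in cfg.cell_lines:
        for st in STATES:
            if st in cl.states:
                groups.append((cl.name, st))
    sample_names: list[str] = []
    meta_rows: list[dict] = []
    for cl_name, st in groups:
        for r in range(1, cfg.replicates + 1):
            sample_names.append(f"{cl_name}_{st}_r{r}")
            meta_rows.append({"cell_line": cl_name, "state": st, "replicate": r})
    sample_meta = pd.DataFrame(meta_rows, index=pd.Index(sample_names, name="sample"))

    mech = {cl.name: cl.mechanism for cl in cfg.cell_lines}

    # per-protein planted effect per (line, state)
    eff_cols = [f"{cl}:{st}" for cl, st in groups]
    eff = pd.DataFrame(0.0, index=proteins, columns=eff_cols)
    for prog in PROGRAMS:
        for cl_name, st in groups:
            e = _program_effect(cfg, prog, mech[cl_name], st)
            if e != 0.0:
                eff.loc[list(programs[prog]), f"{cl_name}:{st}"] += e

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_feat)
    prot_index = pd.Index(proteins)
    prot_pos = prot_index.get_indexer(f_prot)

    values = np.empty((n_feat, len(sample_names)))
    col = 0
    eff_arr = eff.to_numpy()
    for gi, (cl_name, st) in enumerate(groups):
        group_eff = eff_arr[prot_pos, gi]
        for _ in range(cfg.replicates):
            noise = (
                rng.normal(0.0, cfg.noise_sd, size=n_feat) if cfg.noise_sd > 0 else np.zeros(n_feat)
            )
            values[:, col] = baseline + group_eff + noise
            col += 1

    if cfg.missing_midpoint is not None:
        p_det = _detection_prob(values, cfg.missing_midpoint, cfg.missing_scale)
        detected = rng.random(values.shape) < p_det
        values = np.where(detected, values, np.nan)

    vdf = pd.DataFrame(values, index=pd.Index(fids, name="feature_id"), columns=sample_names)
    fmeta = pd.DataFrame(
        {"protein_id": f_prot, "site_label": f_site}, index=pd.Index(fids, name="feature_id")
    )
    table = QuantTable(values=vdf, feature_meta=fmeta, sample_meta=sample_meta, scale="log2")

    # gene sets: planted programs, decoys of matched sizes, site-level substrates
    sets: dict[str, tuple[str, ...]] = {p: programs[p] for p in PROGRAMS if programs[p]}
    all_dirs = {
        "shared_up": "up",
        "persistent_down": "down",
        "resistant_up": "up",
        "resistant_down": "down",
    }
    direction = {k: v for k, v in all_dirs.items() if k in sets}
    # decoys are random draws from the FULL universe so they are
    # exchangeable with planted sets under zero effect
    sizes = [s for s in (cfg.n_shared_up, cfg.n_persistent_down,
                         cfg.n_resistant_up, cfg.n_resistant_down) if s > 0] or [20]
    for i in range(cfg.n_decoy_sets):
        size = min(sizes[i % len(sizes)], cfg.n_proteins)
        pick = rng.choice(cfg.n_proteins, size=size, replace=False)
        sets[f"decoy_{i:02d}"] = tuple(sorted(proteins[j] for j in pick))
        direction[f"decoy_{i:02d}"] = "undirected"

    # site-level substrate sets: planted kinase = sites of shared_up proteins
    fid_by_prot: dict[str, list[str]] = {}
    for fid, p in zip(fids, f_prot):
        fid_by_prot.setdefault(p, []).append(fid)
    kin_sites = tuple(s for p in programs["shared_up"] for s in fid_by_prot[p])
    if kin_sites:
        sets["substrates_shared_kinase"] = kin_sites
        direction["substrates_shared_kinase"] = "up"
        for i in range(cfg.n_decoy_sets):
            pick = rng.choice(n_feat, size=min(len(kin_sites), 30), replace=False)
            sets[f"substrates_decoy_{i:02d}"] = tuple(sorted(fids[j] for j in pick))
            direction[f"substrates_decoy_{i:02d}"] = "undirected"

    collection = GeneSetCollection(sets=sets, direction=direction)
    truth = GroundTruth(programs=programs, protein_effects=eff, config=cfg)
    return table, collection, truth


def make_expression_twin(truth: GroundTruth, config: SimulationConfig | None = None) -> QuantTable:
    """Gene-expression counterpart of a simulated experiment.

    One expression row per protein; planted effects are inherited from the
    protein-level ground truth, with independent Gaussian noise
    (``expression_noise_sd``) under the same seed discipline (a child seed
    derived from ``config.seed``, so the twin is deterministic but its
    noise is independent of the proteomic noise).
    """
    cfg = config or truth.config
    if list(truth.protein_effects.index) != [f"P{i:05d}" for i in range(cfg.n_proteins)]:
        raise ValueError("ground truth does not match config protein universe")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    proteins = list(truth.protein_effects.index)
    groups = [tuple(c.split(":")) for c in truth.protein_effects.columns]
    sample_names: list[str] = []
    meta_rows: list[dict] = []
    for cl_name, st in groups:
        for r in range(1, cfg.replicates + 1):
            sample_names.append(f"{cl_name}_{st}_x{r}")
            meta_rows.append({"cell_line": cl_name, "state": st, "replicate": r})
    sample_meta = pd.DataFrame(meta_rows, index=pd.Index(sample_names, name="sample"))

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(proteins))
    eff_arr = truth.protein_effects.to_numpy()
    values = np.empty((len(proteins), len(sample_names)))
    col = 0
    for gi in range(len(groups)):
        for _ in range(cfg.replicates):
            noise = (
                rng.normal(0.0, cfg.expression_noise_sd, size=len(proteins))
                if cfg.expression_noise_sd > 0
                else np.zeros(len(proteins))
            )
            values[:, col] = baseline + eff_arr[:, gi] + noise
            col += 1

    vdf = pd.DataFrame(values, index=pd.Index(proteins, name="feature_id"), columns=sample_names)
    fmeta = pd.DataFrame(
        {"protein_id": proteins, "site_label": [""] * len(proteins)},
        index=pd.Index(proteins, name="feature_id"),
    )
    return QuantTable(values=vdf, feature_meta=fmeta, sample_meta=sample_meta, scale="log2")
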