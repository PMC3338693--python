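"""End-to-end orchestration: simulate (or load) -> characterize -> infer ->
score -> topology tests, as one reproducible, seeded run.

Every stage writes plain-text outputs under the run directory
(``characterize/``, ``trees/``, ``score/``, ``tests/``) plus a manifest and
a log; the whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import seqchar
from .congruence import rank_genes, reference_nodes, score_gene
from .consensus import (
    bootstrap_support,
    majority_rule_consensus,
    same_unrooted_topology,
    _infer_one,
)
from .likelihood import (
    ModelFitResult,
    PruningEngine,
    optimize_branch_lengths,
    select_model_aic,
)
from .models import SubstitutionModel, model_from_id
from .njoin import nj_tree
from .seqio import (
    Alignment,
    Locus,
    concatenate,
    read_alignment,
    write_alignment,
    write_partition_table,
    write_tree,
)
from .synth import (
    DEFAULT_OUTGROUP,
    SimulationConfig,
    StudyBundle,
    generate_study,
)
from .topotests import SiteLnLMatrix, kh_test, sh_test
from .trees import Tree

__all__ = ["RunConfig", "RunResult", "run_pipeline", "bootstrap_consensus_tree"]


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"  # {"synthetic", "replay"}
    out_dir: str = "out"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    replay_dir: Optional[str] = None  # directory of per-locus FASTA files
    gene_method: str = "mp"
    gene_bootstrap: int = 100
    combined_method: str = "mp"
    combined_bootstrap: int = 100
    model_policy: str = "aic"  # {"aic", "fixed"}
    model_selection_max_sites: int = 2000
    fixed_nuclear_model: str = "HKY85+G"
    fixed_mt_model: str = "GTR+I+G"
    support_threshold: float = 0.95
    outgroup: tuple[str, ...] = DEFAULT_OUTGROUP
    sh_resamples: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("synthetic", "replay"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "replay" and not self.replay_dir:
            raise ValueError("replay mode needs replay_dir")
        if self.mode == "replay" and not Path(self.replay_dir).is_dir():
            raise ValueError(f"replay_dir does not exist: {self.replay_dir}")


@dataclass
class RunResult:
    config: RunConfig
    out_dir: Path
    bundle: Optional[StudyBundle]
    characterization: pd.DataFrame
    gene_trees: dict[str, Tree]
    combined_trees: dict[str, Tree]
    performances: pd.DataFrame
    topo_tests: pd.DataFrame
    models: dict[str, SubstitutionModel]


def bootstrap_consensus_tree(
    alignment: Alignment,
    method: str = "mp",
    replicates: int = 100,
    seed: int = 0,
    model=None,
) -> Tree:
    """Majority-rule consensus of bootstrap-replicate trees, supports =
    replicate frequencies (the per-gene tree used for congruence scoring,
    standing in for a per-gene Bayesian consensus)."""
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates + 1)]
    rng = np.random.default_rng(child[0])
    reps = []
    for b in range(replicates):
        idx = rng.integers(0, alignment.n_cols, size=alignment.n_cols)
        rep = alignment.columns(list(idx))
        reps.append(_infer_one(rep, method, child[b + 1], model))
    return majority_rule_consensus(reps)


def _select_model(
    alignment: Alignment, config: RunConfig, fallback_id: str, seed: int
) -> tuple[SubstitutionModel, str]:
    if config.model_policy == "fixed":
        return model_from_id(fallback_id, alpha=0.7), fallback_id
    cols = alignment.n_cols
    if cols > config.model_selection_max_sites:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(cols, size=config.model_selection_max_sites, replace=False))
        sub = alignment.columns(idx)
    else:
        sub = alignment
    base = nj_tree(seqchar.pairwise_distance_matrix(sub), sub.labels)
    fits = select_model_aic(sub, base)
    best = fits[0]
    return best.model, best.model_id


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    for sub in ("characterize", "trees", "trees/genetrees", "score", "tests", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    # ------------------------------------------------------------- stage 1
    t0 = time.time()
    bundle: Optional[StudyBundle] = None
    if config.mode == "synthetic":
        sim = replace(config.sim, seed=stage_seeds[0])
        bundle = generate_study(sim)
        loci = bundle.loci
        write_tree(bundle.species_tree, out / "truth" / "species_tree.nwk")
        for name, gt in bundle.gene_trees.items():
            write_tree(gt, out / "truth" / f"{name}.nwk", include_support=False)
        for locus in loci:
            write_alignment(locus.alignment, out / "truth" / f"{locus.name}.fasta")
        log("simulate", f"{len(loci)} loci seed={stage_seeds[0]} wall={time.time()-t0:.1f}s")
    else:
        loci = _load_replay_loci(Path(config.replay_dir))
        log("load", f"{len(loci)} replay loci from {config.replay_dir}")

    nuclear = [l for l in loci if l.locus_class == "nuclear_noncoding"]
    mt = [l for l in loci if l.locus_class.startswith("mt_")]

    # ------------------------------------------------------------- stage 2
    t0 = time.time()
    rows = []
    for locus in loci:
        row = seqchar.characterize_locus(locus)
        rows.append({"set": "nuclear" if locus in nuclear else "mt", **row.__dict__})
    combos: dict[str, Alignment] = {}
    partitions = {}
    if nuclear:
        combos["combined_nuclear"], partitions["nuclear"] = concatenate(nuclear)
    if mt:
        combos["combined_mt"], partitions["mt"] = concatenate(mt)
    if nuclear and mt:
        combos["combined_all"], partitions["all"] = concatenate(nuclear + mt)
    for name, aln in combos.items():
        row = seqchar.characterize_locus(Locus(name, aln, "nuclear_noncoding"))
        rows.append({"set": "combined", **row.__dict__})
    characterization = pd.DataFrame(rows)
    characterization.to_csv(out / "characterize" / "table.tsv", sep="\t", index=False)
    for pname, table in partitions.items():
        write_partition_table(table, out / "characterize" / f"partitions_{pname}.txt")
    log("characterize", f"{len(rows)} rows wall={time.time()-t0:.1f}s")

    # ------------------------------------------------------------- stage 3
    t0 = time.time()
    models: dict[str, SubstitutionModel] = {}
    gene_trees: dict[str, Tree] = {}
    gene_seed_root = np.random.SeedSequence(stage_seeds[1])
    gseeds = [int(s.generate_state(1)[0] % (2**31)) for s in gene_seed_root.spawn(len(loci))]
    for locus, gseed in zip(loci, gseeds):
        gene_model = None
        if config.gene_method == "ml":
            fallback = (
                config.fixed_mt_model
                if locus.locus_class.startswith("mt_")
                else config.fixed_nuclear_model
            )
            # per-gene model policy: each locus gets its own AIC pick
            gene_model, gene_model_id = _select_model(
                locus.alignment, config, fallback, gseed
            )
            models[locus.name] = gene_model
        tree = bootstrap_consensus_tree(
            locus.alignment,
            method=config.gene_method,
            replicates=config.gene_bootstrap,
            seed=gseed,
            model=gene_model,
        )
        gene_trees[locus.name] = tree
        write_tree(tree, out / "trees" / "genetrees" / f"{locus.name}.nwk")
    log("infer", f"per-gene {config.gene_method} x{config.gene_bootstrap} wall={time.time()-t0:.1f}s")

    t0 = time.time()
    combined_trees: dict[str, Tree] = {}
    for i, (name, aln) in enumerate(combos.items()):
        fallback = config.fixed_mt_model if name == "combined_mt" else config.fixed_nuclear_model
        seed_i = stage_seeds[2] + i
        model, model_id = _select_model(aln, config, fallback, seed_i)
        models[name] = model
        tree = bootstrap_support(
            aln,
            method=config.combined_method,
            replicates=config.combined_bootstrap,
            seed=seed_i,
            model=model,
        )
        combined_trees[name] = tree
        write_tree(tree, out / "trees" / f"{name}.nwk")
        log("infer", f"{name} model={model_id} wall={time.time()-t0:.1f}s")

    # ------------------------------------------------------------- stage 4
    t0 = time.time()
    perf_rows = []
    scoring = [
        ("nuclear", nuclear, combined_trees.get("combined_nuclear")),
        ("mt", mt, combined_trees.get("combined_mt")),
    ]
    for set_name, set_loci, ref_tree in scoring:
        if ref_tree is None or not set_loci:
            continue
        refs = reference_nodes(ref_tree, config.outgroup)
        perfs = [
            score_gene(
                gene_trees[l.name], refs, threshold=config.support_threshold, locus=l.name
            )
            for l in set_loci
        ]
        for p in rank_genes(perfs):
            perf_rows.append(
                {
                    "set": set_name,
                    "locus": p.locus,
                    "strong": p.n_congruent_strong,
                    "weak": p.n_congruent_weak,
                    "total": p.n_total,
                    "rank": p.rank,
                    "class": p.performance_class,
                    "nodes": ",".join(str(i) for i in sorted(p.recovered_ids)),
                    "n_reference_nodes": len(refs.nodes),
                }
            )
    performances = pd.DataFrame(perf_rows)
    performances.to_csv(out / "score" / "table3.tsv", sep="\t", index=False)
    log("score", f"{len(perf_rows)} gene rows wall={time.time()-t0:.1f}s")

    # ------------------------------------------------------------- stage 5
    t0 = time.time()
    topo_rows = []
    candidates: dict[str, Tree] = {}
    for name, tree in combined_trees.items():
        if not any(same_unrooted_topology(tree, t) for t in candidates.values()):
            candidates[name] = tree
    for dataset in ("combined_nuclear", "combined_mt"):
        if dataset not in combos or len(candidates) < 2:
            continue
        aln = combos[dataset]
        model = models[dataset]
        engine = PruningEngine(aln, model)
        vectors, ids = [], []
        for cname, ctree in candidates.items():
            opt, _ = optimize_branch_lengths(ctree, engine)
            vectors.append(engine.sitewise(opt))
            ids.append(cname)
        matrix = SiteLnLMatrix(tuple(ids), np.vstack(vectors))
        for res in sh_test(matrix, B=config.sh_resamples, seed=stage_seeds[3]):
            topo_rows.append({"dataset": dataset, "test": "SH", **res.__dict__})
        if len(ids) == 2:
            for res in kh_test(matrix, B=config.sh_resamples, seed=stage_seeds[4]):
                topo_rows.append({"dataset": dataset, "test": "KH", **res.__dict__})
    topo_tests = pd.DataFrame(topo_rows)
    topo_tests.to_csv(out / "tests" / "topology_tests.tsv", sep="\t", index=False)
    log("topotest", f"{len(topo_rows)} rows wall={time.time()-t0:.1f}s")

    # ------------------------------------------------------------ manifest
    manifest = pd.DataFrame(bundle.manifest) if bundle is not None else pd.DataFrame(
        [{"locus": l.name, "locus_class": l.locus_class, "length": l.alignment.n_cols} for l in loci]
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    _write_flat_config(config, out / "config.txt")
    log_path.write_text("\n".join(log_lines) + "\n")
    return RunResult(
        config=config,
        out_dir=out,
        bundle=bundle,
        characterization=characterization,
        gene_trees=gene_trees,
        combined_trees=combined_trees,
        performances=performances,
        topo_tests=topo_tests,
        models=models,
    )


def _load_replay_loci(replay_dir: Path) -> list[Locus]:
    classes = {}
    class_file = replay_dir / "classes.tsv"
    if class_file.exists():
        for line in class_file.read_text().splitlines():
            if line.strip():
                name, cls = line.split("\t")
                classes[name] = cls
    loci = []
    for path in sorted(replay_dir.glob("*.fasta")):
        name = path.stem
        aln = read_alignment(path, "fasta")
        loci.append(Locus(name, aln, classes.get(name, "nuclear_noncoding")))
    if not loci:
        raise ValueError(f"no .fasta loci found in {replay_dir}")
    return loci


def _write_flat_config(config: RunConfig, path: Path) -> None:
    lines = []
    for key, value in config.__dict__.items():
        if key == "sim":
            sim = value
            for skey in (
                "n_nuclear_loci",
                "nuclear_length_range",
                "nuclear_rate_scale",
                "mt_rate_scale",
                "introgression_scope",
            ):
                lines.append(f"sim.{skey}={getattr(sim, skey)}")
            lines.append(f"sim.introgression={'yes' if sim.introgression else 'no'}")
        else:
            lines.append(f"{key}={value}")
    path.write_text("\n".join(lines) + "\n")
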