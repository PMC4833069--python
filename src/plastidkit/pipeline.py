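"""End-to-end orchestration and bundled synthetic fixture configurations.

Two fixtures are provided: ``toy8`` (20 kb, 8 taxa, one hybridization event
and one planted large deletion — fast enough for CI-style runs) and
``citrus34`` (160 kb, 34 taxa in 11 clades echoing the breadth of a citrus
chloroplast panel).  Both are fully determined by a master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chrono, hetero, io as pkio, phylo, selection, simulate, sv, variants

log = logging.getLogger("plastidkit")

TOY8_TREE = "(((A:2,H:2):2,B:4):6,((C:3,D:3):4,(E:5,(F:2.5,G:2.5):2.5):2):3);"


def toy8_config(seed: int = 0) -> simulate.SimulationConfig:
    """8 taxa, 20 kb, root age 10 My; H is a hybrid with donor C (5% leakage)."""
    return simulate.SimulationConfig(
        genome_length=20_000,
        ir_intervals=((12_000, 14_000), (16_000, 18_000)),
        homolog_tracts=[(1_000, 1_200)],
        tree=TOY8_TREE,
        subst_rate=5e-4,
        indel_rate=1e-4,
        large_deletions=[simulate.LargeDeletion("TCCT", 9_325, 9_531, leaf="F", residual=0.05)],
        hybrid_events=[simulate.HybridEvent(recipient="H", donor="C", leakage=0.05)],
        coverage=2_000.0,
        error_rate=0.001,
        seed=seed,
        n_genes=12,
        gene_length=300,
    )


def _citrus34_tree() -> str:
    """34 leaves in 11 clades, ultrametric with root age 13 My."""
    cit = "((cit1:1,cit2:1):1,(cit3:1,cit4:1):1):7"
    aus = "((aus1:1.5,aus2:1.5):0.5,aus3:2):7"
    clade_a = f"({cit},{aus}):2"  # citron/Australian split at 9 My
    pum = "((pum1:1,pum2:1):0.5,pum3:1.5):5.5"
    mic = "(mic1:1,mic2:1):6"
    b1 = f"({pum},{mic}):2"  # pummelo/micrantha at 7 My
    man = (
        "(((man1:0.8,man2:0.8):0.4,(man3:0.8,man4:0.8):0.4):0.8,"
        "((man5:0.8,man6:0.8):0.4,(man7:0.8,man8:0.8):0.4):0.8):3"
    )
    pap = "(pap1:1,pap2:1):4"
    b2a = f"({man},{pap}):2"  # mandarin/papeda at 5 My
    lem = "((lem1:0.7,lem2:0.7):0.8,lem3:1.5):1.5"
    ora = "(ora1:0.6,ora2:0.6):2.4"
    b2b1 = f"({lem},{ora}):2"
    kum = "(kum1:1.2,kum2:1.2):1.8"
    pon = "(pon1:1.3,pon2:1.3):1.7"
    b2b2 = f"({kum},{pon}):2"
    b2b = f"({b2b1},{b2b2}):2"
    b2 = f"({b2a},{b2b}):2"
    b = f"({b1},{b2}):2"
    ingroup = f"({clade_a},{b}):2"  # ingroup radiation at 11 My
    out = "((out1:1,out2:1):0.5,out3:1.5):11.5"
    return f"({ingroup},{out});"


def citrus34_config(seed: int = 0) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        genome_length=160_129,
        ir_intervals=((88_000, 114_000), (133_000, 160_000)),
        homolog_tracts=[(5_000, 5_400), (40_000, 40_250)],
        tree=_citrus34_tree(),
        subst_rate=1.2e-4,
        indel_rate=2.5e-5,
        large_deletions=[
            simulate.LargeDeletion("TCCT", 9_325, 9_531, leaf="aus1", residual=0.03),
            simulate.LargeDeletion("AAAAAAAAA", 13_943, 14_330, leaf="cit1", residual=0.02),
        ],
        hybrid_events=[simulate.HybridEvent(recipient="lem1", donor="cit2", leakage=0.04)],
        coverage=2_000.0,
        error_rate=0.001,
        seed=seed,
        n_genes=20,
        gene_length=300,
    )


FIXTURES = {"toy8": toy8_config, "citrus34": citrus34_config}


def write_fixtures(name: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write the named synthetic dataset (data + truth + config) to ``outdir``."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    cfg = FIXTURES[name](seed=seed)
    ds = simulate.simulate_dataset(cfg)
    outdir = Path(outdir) / name
    simulate.write_dataset(ds, cfg, outdir)
    return outdir


@dataclass
class PipelineConfig:
    """Stage toggles, thresholds and the master seed for one pipeline run."""

    seed: int = 0
    fixture: str = "toy8"
    stages: dict = field(
        default_factory=lambda: {
            "variants": True,
            "hetero": True,
            "phylo": True,
            "dating": False,
            "selection": False,
            "sv": True,
        }
    )
    thresholds: variants.ThresholdConfig = field(default_factory=variants.ThresholdConfig)
    shp_min_minor: int = 5
    shp_min_depth: int = 1000
    sv_min_len: int = 50
    sv_drop_ratio: float = 0.2
    selection_alpha: float = 0.05
    selection_min_subs: float = 5.0
    dating_lambda: float | str = 1.0
    n_boot: int = 100

    def validate(self) -> None:
        if not any(self.stages.values()):
            raise ValueError("no stage selected")


@dataclass
class PipelineResult:
    summary: dict
    matrix: variants.VariantMatrix | None = None
    annotations: pd.DataFrame | None = None
    shp_records: list = field(default_factory=list)
    tree: object | None = None
    dating: chrono.DatingResult | None = None
    selection_table: pd.DataFrame | None = None
    sv_calls: list = field(default_factory=list)
    dataset: simulate.SimulatedDataset | None = None

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(self.summary, sort_keys=True, default=str).encode()
        ).hexdigest()


def run_pipeline(cfg: PipelineConfig, dataset: simulate.SimulatedDataset | None = None) -> PipelineResult:
    """Run the enabled stages end-to-end on a simulated (or given) dataset."""
    cfg.validate()
    if dataset is None:
        sim_cfg = FIXTURES[cfg.fixture](seed=cfg.seed)
        dataset = simulate.simulate_dataset(sim_cfg)
    res = PipelineResult(summary={}, dataset=dataset)
    summary = res.summary
    summary["seed"] = cfg.seed

    matrix = None
    if cfg.stages.get("variants"):
        log.info("stage variants")
        matrix = variants.build_variant_matrix(
            dataset.pileups, dataset.reference, dataset.mask, cfg.thresholds
        )
        res.matrix = matrix
        res.annotations = variants.classify_variants(matrix, dataset.genes, dataset.reference)
        summary["variants"] = variants.summarize_variants(matrix, res.annotations)

    if cfg.stages.get("hetero"):
        if matrix is None:
            summary["hetero"] = {"skipped": "variants stage required"}
        else:
            log.info("stage hetero")
            shp = hetero.call_shp(
                dataset.pileups, matrix.snv_positions(), cfg.shp_min_minor, cfg.shp_min_depth
            )
            res.shp_records = shp
            summary["hetero"] = {"n_shp": len(shp), "samples": sorted({r.sample for r in shp})}

    tree = None
    if cfg.stages.get("phylo"):
        if matrix is None:
            summary["phylo"] = {"skipped": "variants stage required"}
        else:
            log.info("stage phylo")
            aln = phylo.concat_variable_sites(matrix)
            tree = phylo.nj_bootstrap_tree(aln, n_boot=cfg.n_boot, seed=cfg.seed)
            res.tree = tree
            summary["phylo"] = {"n_sites": aln.n_sites, "n_taxa": len(aln.samples)}

    if cfg.stages.get("dating") and tree is not None:
        log.info("stage dating")
        aln = phylo.concat_variable_sites(matrix)
        rooted = tree
        counts = chrono.branch_counts(rooted, aln.n_sites)
        constraints = chrono.DatingConstraints(root_age=10.0)
        lam = cfg.dating_lambda
        if lam == "cv":
            lam, _ = chrono.cross_validate_lambda(rooted, counts, constraints)
        fit = chrono.fit_pl(rooted, counts, constraints, float(lam))
        res.dating = fit
        summary["dating"] = {"lambda": float(lam), "converged": fit.converged}

    if cfg.stages.get("selection"):
        log.info("stage selection")
        sel_tree = dataset.tree
        table = selection.selection_scan(
            dataset.genomes,
            dataset.genes,
            sel_tree,
            ir_intervals=list(FIXTURES[cfg.fixture](seed=cfg.seed).ir_intervals),
            alpha=cfg.selection_alpha,
            min_subs=cfg.selection_min_subs,
        )
        res.selection_table = table
        summary["selection"] = {"n_tests": int(len(table))}

    if cfg.stages.get("sv"):
        log.info("stage sv")
        calls = []
        for sample in sorted(dataset.pileups["sample"].unique()):
            try:
                calls.extend(
                    sv.detect_deletions(
                        dataset.pileups,
                        sample=sample,
                        min_sv_len=cfg.sv_min_len,
                        drop_ratio=cfg.sv_drop_ratio,
                        reference=dataset.reference,
                    )
                )
            except ValueError as exc:
                log.warning("sv stage failed for %s: %s", sample, exc)
        for c in calls:
            sv.annotate_breakpoint_homology(dataset.reference, c)
        res.sv_calls = calls
        summary["sv"] = {
            "n_calls": len(calls),
            "calls": [
                {"sample": c.sample, "start": c.start, "end": c.end, "het": c.heteroplasmic}
                for c in calls
            ],
        }
    return res
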