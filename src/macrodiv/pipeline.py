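"""End-to-end orchestration: run every diversification analysis on one
configuration and collect the results in a serialisable report.

The stage order mirrors a complete macroevolutionary study of a clade:
CR/gamma test -> MCCR incomplete-sampling correction -> birth-death model
selection -> Monte-Carlo delta-AIC significance -> among-clade rate-shift
search on a richness backbone -> trait-dependent diversification test
(BiSSE) -> ancestral state reconstruction.  Stages run independently: a
failure is recorded and the remaining stages still execute.  All
randomness is driven by explicit per-stage seeds derived from the config
seed, so a rerun reproduces the report numerically.
"""

from __future__ import annotations

import importlib.resources
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tree import (TimeTree, read_newick, read_newick_list,
                   read_tip_annotations, read_clade_richness)
from .simulate import (simulate_multirate_yule, simulate_mk_characters,
                       simulate_yule)
from .gamma import cr_test_tree, MCCRTest, mccr_alpha_sweep, gamma_of_tree
from .bdl import BDLModel, delta_aic_significance
from .medusa import Medusa, sample_clade_richness
from .bisse import BisseModel, lrt_equal_lambda, binarize_ecology
from .ancstate import MkAncestralModel, stochastic_map

__all__ = ["AnalysisConfig", "RunReport", "run_full_analysis",
           "render_tables", "write_demo_inputs", "packaged_table"]

STAGES = ("gamma", "mccr", "bdl", "delta_aic", "medusa", "bisse", "asr")


def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the CSV tables shipped with the package
    (``clade_richness``, ``backbone_richness``, ``state_codes``)."""
    ref = importlib.resources.files("macrodiv.data") / f"{name}.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass
class AnalysisConfig:
    """Configuration of a full run (mirrors the YAML config file)."""
    tree: str | None = None                 # Newick chronogram (MCC)
    posterior_trees: str | None = None      # optional one-per-line Newick
    annotations: str | None = None          # species,state CSV (ecology)
    richness_table: str | None = None       # clade,richness CSV (backbone)
    backbone: str | None = None             # Newick backbone for MEDUSA
    n_total: int | None = None              # true clade richness for MCCR
    B: int = 5000                           # Monte-Carlo replicates
    seed: int = 0
    significance: float = 0.05
    medusa_threshold: float = 4.0
    medusa_max_shifts: int = 5
    alpha_grid: tuple = ()
    asr_states: int | None = None
    simmap_draws: int = 50
    stages: tuple = STAGES
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("stages", "alpha_grid"):
            setattr(cfg, key, tuple(getattr(cfg, key) or ()))
        return cfg

    def validate(self) -> list[str]:
        """All problems at once, before any stage runs."""
        errors = []
        for key in ("tree", "posterior_trees", "annotations",
                    "richness_table", "backbone"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                errors.append(f"{key}: file not found: {p}")
        if self.tree is None:
            errors.append("tree: a chronogram is required")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            errors.append(f"stages: unknown {sorted(unknown)}")
        if "mccr" in self.stages and self.n_total is None:
            errors.append("n_total: required for the mccr stage")
        if "delta_aic" in self.stages and self.n_total is None:
            errors.append("n_total: required for the delta_aic stage")
        if "medusa" in self.stages and (self.backbone is None
                                        or self.richness_table is None):
            errors.append("medusa stage needs 'backbone' and "
                          "'richness_table'")
        if "bisse" in self.stages and self.annotations is None:
            errors.append("bisse stage needs 'annotations'")
        if "asr" in self.stages and self.annotations is None:
            errors.append("asr stage needs 'annotations'")
        if self.B < 100:
            errors.append("B must be >= 100")
        return errors


@dataclass
class RunReport:
    """Per-stage records plus provenance; losslessly JSON-serialisable."""
    records: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    wall_clock: float = 0.0

    def to_json(self, **kwargs) -> str:
        return json.dumps({"records": self.records, "errors": self.errors,
                           "seeds": self.seeds, "version": self.version,
                           "wall_clock": self.wall_clock},
                          indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(records=d["records"], errors=d["errors"],
                   seeds=d["seeds"], version=d["version"],
                   wall_clock=d["wall_clock"])

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "report.json"
        path.write_text(self.to_json(sort_keys=True))
        for name, text in render_tables(self).items():
            (outdir / f"{name}.txt").write_text(text)
        return path


def _stage_seed(base: int, stage: str) -> int:
    # stable per-stage stream, recorded in the report
    return (int(base) * 1009 + STAGES.index(stage) * 101) % (2 ** 31)


def run_full_analysis(config: AnalysisConfig) -> RunReport:
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    t_start = time.time()
    report = RunReport()
    tree = read_newick(config.tree)
    posterior = (read_newick_list(config.posterior_trees)
                 if config.posterior_trees else None)
    annot = (read_tip_annotations(config.annotations)
             if config.annotations else None)

    def run_stage(name, fn):
        if name not in config.stages:
            return
        seed = _stage_seed(config.seed, name)
        report.seeds[name] = seed
        try:
            report.records[name] = fn(seed)
        except Exception as exc:
            report.errors[name] = f"{type(exc).__name__}: {exc}"

    def stage_gamma(seed):
        res = cr_test_tree(tree)
        rec = {"gamma": res.gamma, "n": res.n, "p_value": res.p_value}
        if posterior:
            gs = np.array([gamma_of_tree(t) for t in posterior])
            rec["posterior_mean"] = float(gs.mean())
            rec["posterior_median"] = float(np.median(gs))
            rec["posterior_range"] = [float(gs.min()), float(gs.max())]
        return rec

    def stage_mccr(seed):
        obs = posterior if posterior else tree
        res = MCCRTest(obs, config.n_total, n_sampled=tree.n_tips,
                       B=config.B,
                       significance=config.significance).fit(seed)
        rec = {"observed_gamma": res.observed_gamma,
               "n_total": res.n_total, "n_sampled": res.n_sampled,
               "B": res.B, "critical_gamma": res.critical_value,
               "p_value": res.p_value, "significant": bool(res.significant),
               "seed": seed}
        if config.alpha_grid:
            sweep = mccr_alpha_sweep(res.observed_gamma, config.n_total,
                                     config.alpha_grid,
                                     B=max(config.B // 5, 200), seed=seed,
                                     n_sampled=tree.n_tips)
            rec["alpha_sweep"] = sweep.to_dict(orient="records")
        return rec

    def stage_bdl(seed):
        res = BDLModel(tree).fit()
        rec = {"best_model": res.best_model,
               "delta_aic_rc_rv": res.delta_aic_rc_rv,
               "models": {m: {"params": f.params, "lnL": f.lnL,
                              "k": f.k, "AIC": f.aic,
                              "dAIC": res.delta_aic[m]}
                          for m, f in res.fits.items()}}
        return rec

    def stage_delta_aic(seed):
        obs = BDLModel(tree).fit().delta_aic_rc_rv
        p = delta_aic_significance(obs, config.n_total, tree.n_tips,
                                   B=config.B, seed=seed)
        return {"observed_delta_aic": obs, "p_value": p,
                "n_total": config.n_total, "n_sampled": tree.n_tips,
                "B": config.B, "seed": seed}

    def stage_medusa(seed):
        backbone = read_newick(config.backbone)
        rich = read_clade_richness(config.richness_table)
        res = Medusa(backbone, richness=rich).fit(
            max_shifts=config.medusa_max_shifts,
            threshold=config.medusa_threshold)
        return {"n_shifts": res.n_shifts, "lnL": res.lnL, "k": res.k,
                "AIC": res.aic,
                "regimes": [{"clade": (list(r.shift_clade)
                                       if r.shift_clade else "base"),
                             "r": r.r, "eps": r.eps,
                             "n_terminals": r.n_terminals}
                            for r in res.regimes],
                "history": [[d, a] for d, a in res.history]}

    def stage_bisse(seed):
        states = binarize_ecology(annot)
        model = BisseModel(tree, states)
        fit_c = model.fit(constrained=True)
        fit_u = model.fit(constrained=False)
        stat, p = lrt_equal_lambda(fit_u, fit_c)
        return {"unconstrained": {"params": asdict(fit_u.params),
                                  "lnL": fit_u.lnL},
                "constrained": {"params": asdict(fit_c.params),
                                "lnL": fit_c.lnL},
                "lrt_statistic": stat, "p_value": p}

    def stage_asr(seed):
        model = MkAncestralModel(tree, annot, K=config.asr_states)
        rec = model.fit()
        out = {"method": "ML marginal (Mk1)", "rate": rec.rate,
               "lnL": rec.lnL,
               "nodes": [{"clade": sorted(c), "PL": [round(float(v), 4)
                                                     for v in p]}
                         for c, p in sorted(rec.node_probs.items(),
                                            key=lambda kv: -len(kv[0]))]}
        if posterior:
            summ = stochastic_map(posterior[:100], annot,
                                  K=config.asr_states,
                                  n_draws=config.simmap_draws, seed=seed)
            out["simmap"] = [{"clade": sorted(c),
                              "trees": summ.tree_count[c],
                              "MPP": [round(float(v), 4)
                                      for v in summ.mpp[c]]}
                             for c in sorted(summ.mpp,
                                             key=lambda c: -len(c))]
        return out

    run_stage("gamma", stage_gamma)
    run_stage("mccr", stage_mccr)
    run_stage("bdl", stage_bdl)
    run_stage("delta_aic", stage_delta_aic)
    run_stage("medusa", stage_medusa)
    run_stage("bisse", stage_bisse)
    run_stage("asr", stage_asr)

    report.wall_clock = time.time() - t_start
    if config.outdir:
        report.save(config.outdir)
    return report


# ------------------------------------------------------------- rendering

def render_tables(report: RunReport) -> dict[str, str]:
    """Deterministic text tables per stage (3 decimals for lnL/AIC, 6 for
    gamma and critical values, 2 for PL/MPP)."""
    out = {}
    rec = report.records.get("bdl")
    if rec:
        cols = {}
        for m, f in rec["models"].items():
            cols[m] = {
                "Parameters": " ".join(f"{k} = {v:.3f}"
                                       for k, v in f["params"].items()),
                "Ln(L)": f"{f['lnL']:.3f}",
                "AIC": f"{f['AIC']:.3f}",
                "dAIC": f"{f['dAIC']:.3f}",
            }
        out["bdl_table"] = pd.DataFrame(cols).to_string()
    rec = report.records.get("mccr")
    if rec:
        out["mccr"] = (
            f"MCCR: N_total = {rec['n_total']}, n_sampled = "
            f"{rec['n_sampled']}, B = {rec['B']}, observed gamma = "
            f"{rec['observed_gamma']:.6f}, critical gamma = "
            f"{rec['critical_gamma']:.6f}, P = {rec['p_value']:.4g}")
    rec = report.records.get("gamma")
    if rec:
        out["gamma"] = (f"gamma = {rec['gamma']:.6f} (n = {rec['n']}), "
                        f"one-tailed CR P = {rec['p_value']:.4g}")
    rec = report.records.get("medusa")
    if rec:
        rows = [{"clade": ("base" if r["clade"] == "base"
                           else "+".join(r["clade"])),
                 "r": f"{r['r']:.3f}", "eps": f"{r['eps']:.3f}",
                 "tips": r["n_terminals"]} for r in rec["regimes"]]
        out["medusa"] = (f"shifts = {rec['n_shifts']}, AIC = "
                         f"{rec['AIC']:.3f}\n"
                         + pd.DataFrame(rows).to_string(index=False))
    rec = report.records.get("bisse")
    if rec:
        u, c = rec["unconstrained"], rec["constrained"]
        out["bisse"] = (
            "BiSSE speciation-rate test\n"
            f"  unconstrained lnL = {u['lnL']:.3f} "
            f"(lam0 = {u['params']['lam0']:.4f}, "
            f"lam1 = {u['params']['lam1']:.4f})\n"
            f"  constrained   lnL = {c['lnL']:.3f}\n"
            f"  LRT = {rec['lrt_statistic']:.3f}, chi2(1) P = "
            f"{rec['p_value']:.4g}")
    rec = report.records.get("asr")
    if rec:
        def short(labels):
            s = "+".join(labels)
            return s if len(s) <= 48 else s[:45] + "..."
        rows = [{"clade": short(nd["clade"]), "n_tips": len(nd["clade"]),
                 "state": int(np.argmax(nd["PL"])),
                 "PL": f"{max(nd['PL']):.2f}"} for nd in rec["nodes"]]
        out["asr"] = pd.DataFrame(rows).to_string(index=False)
    return out


# ----------------------------------------------------------------- demo

def write_demo_inputs(outdir, seed: int = 0, n_tips: int = 218) -> dict:
    """Generate a self-contained synthetic input set and YAML config.

    The chronogram is a two-rate pure-birth tree (a known slowdown), the
    ecology character evolves under Mk on it, the MEDUSA backbone is a
    13-terminal tree carrying the packaged richness table, and the config
    mirrors the standard analysis settings.  Returns the config path plus
    the generating parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    tree = simulate_multirate_yule(n_tips, [0.35, 0.12], [8.0],
                                   seed=int(rng.integers(2 ** 31)))
    tree_path = outdir / "chronogram.nwk"
    tree_path.write_text(tree.to_newick())

    q = 0.6 / tree.crown_age
    Q = np.full((6, 6), q / 5.0)
    np.fill_diagonal(Q, -q)
    states = simulate_mk_characters(tree, Q,
                                    seed=int(rng.integers(2 ** 31)))
    annot_path = outdir / "ecology.csv"
    pd.DataFrame({"species": list(states), "state": list(states.values())}
                 ).to_csv(annot_path, index=False)

    rich = packaged_table("backbone_richness")
    backbone = simulate_yule(len(rich), 0.12,
                             seed=int(rng.integers(2 ** 31)))
    relab = dict(zip(sorted(backbone.tip_labels,
                            key=lambda l: int(l[1:])), rich["clade"]))
    for lf in backbone.dendropy_tree.leaf_node_iter():
        lf.taxon.label = relab[lf.taxon.label]
    backbone._index()
    backbone_path = outdir / "backbone.nwk"
    backbone_path.write_text(backbone.to_newick())
    rich_path = outdir / "richness.csv"
    rich.to_csv(rich_path, index=False)

    config = {
        "tree": str(tree_path),
        "annotations": str(annot_path),
        "backbone": str(backbone_path),
        "richness_table": str(rich_path),
        "n_total": 4 * n_tips,
        "B": 500,
        "seed": int(seed),
        "outdir": str(outdir / "results"),
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return {"config": str(cfg_path), "tree": str(tree_path),
            "true_rates": [0.35, 0.12],
            "true_shift_ages": list(tree.shift_ages)}
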