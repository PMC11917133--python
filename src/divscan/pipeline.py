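"""End-to-end orchestration: simulate/load -> filter -> windowed stats ->
sweep scan -> outliers -> permutation tests -> enrichment -> report.

Every random stage receives its own child seed spawned deterministically
from the run seed, so stages can be reordered or rerun in isolation
without reseeding collisions, and the whole run is reproducible bit for
bit from the config.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io as dio
from . import outliers as out
from . import resampling as res
from . import simulate as sim
from . import sweep as swp
from . import windows as win
from .pca import pca_quicklook

log = logging.getLogger("divscan")


@dataclass
class RunConfig:
    """All thresholds of a run; the defaults are the scan's canonical values
    (500-kb FST/d_XY windows, 100-kb pi windows, top 2% differentiation
    outliers, CLR grid of 1,000 with top 0.05% and >= 2 consecutive grids,
    100 / 1,000 permutation replications, FDR < 0.1)."""

    window_size: int = 500_000
    pi_window_size: int = 100_000
    fst_outlier_fraction: float = 0.02
    dxy_outlier_fraction: float = 0.02
    clr_outlier_fraction: float = 0.0005
    grid: int = 1000
    max_window: int = 1_000_000
    fst_perm_reps: int = 100
    association_reps: int = 1000
    fdr: float = 0.1
    drop_missing: bool = True
    seed: int = 0
    outdir: str = "divscan_out"

    def __post_init__(self) -> None:
        for frac in (self.fst_outlier_fraction, self.dxy_outlier_fraction,
                     self.clr_outlier_fraction, self.fdr):
            if not (0.0 < frac < 1.0):
                raise ValueError("fractions must lie in (0, 1)")
        if self.window_size <= 0 or self.pi_window_size <= 0 or self.grid <= 0:
            raise ValueError("sizes and grid must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def reference_config(seed: int = 0, outdir: str = "divscan_out") -> RunConfig:
    """Desk-scale settings matched to :func:`divscan.simulate.reference_scenario`
    (1-Mb chromosomes: 100-kb scan windows, 20-kb pi windows); every
    fraction, grid and replication count keeps its canonical default."""
    return RunConfig(window_size=100_000, pi_window_size=20_000,
                     seed=seed, outdir=outdir)


def _stage_seeds(seed: int, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(cfg: RunConfig, vt=None, pm=None, ci=None, genes=None,
                 scenario: "sim.SimScenario | None" = None,
                 write: bool = True) -> dict:
    """Run every stage; returns a result dict and (optionally) writes the
    tab-separated tables, BED files and a JSON/text report to cfg.outdir."""
    seeds = _stage_seeds(cfg.seed, ["simulate", "fst_perm", "association"])
    if vt is None:
        if scenario is None:
            scenario = sim.reference_scenario(seeds["simulate"])
        vt, pm, ci, genes, _regions = sim.simulate_scenario(scenario)
    if pm is None or ci is None:
        raise ValueError("pm and ci are required alongside an input VariantTable")
    dio.check_contigs(vt, ci)

    vt = dio.hard_filter_sites(vt)
    n_after_hard = vt.n_sites
    if cfg.drop_missing:
        vt = dio.drop_missing_sites(vt)
    log.info("sites after filtering: %d", vt.n_sites)

    pops = pm.populations
    pairs = list(itertools.combinations(pops, 2))
    windows = win.make_windows(ci, cfg.window_size)
    pi_windows = win.make_windows(ci, cfg.pi_window_size)

    pi_fine = win.window_pi(vt, pm, pi_windows)
    pi_coarse = win.aggregate_windows(
        pi_fine, windows, [f"pi_{p}" for p in pops])

    pair_stats: dict[tuple, pd.DataFrame] = {}
    theta_genome: dict[tuple, float] = {}
    fst_perm: dict[tuple, res.PermutationResult] = {}
    tau: dict[tuple, tuple] = {}
    ogd_by_pair: dict[tuple, set] = {}
    flags_by_pair: dict[tuple, pd.DataFrame] = {}
    for a, b in pairs:
        fst = win.wc_fst(vt, pm, a, b, windows)
        dxy = win.window_dxy(vt, pm, windows, a, b)
        stats = fst.rename(columns={"n_sites": "n_sites_fst"})
        stats["dxy"] = dxy["dxy"]
        stats["n_sites_dxy"] = dxy["n_sites"]
        stats[f"pi_{a}"] = pi_coarse[f"pi_{a}"]
        stats[f"pi_{b}"] = pi_coarse[f"pi_{b}"]
        pair_stats[(a, b)] = stats
        theta_genome[(a, b)] = win.wc_fst(vt, pm, a, b)
        fst_perm[(a, b)] = res.fst_label_permutation(
            vt, pm, a, b, reps=cfg.fst_perm_reps, seed=seeds["fst_perm"])
        mean_pi = (stats[f"pi_{a}"] + stats[f"pi_{b}"]) / 2.0
        ok = stats["dxy"].notna() & mean_pi.notna()
        tau[(a, b)] = win.kendall_tau(stats.loc[ok, "dxy"], mean_pi[ok])
        _, _, ogd, flags = out.outlier_calls(stats, cfg.fst_outlier_fraction)
        ogd_by_pair[(a, b)] = ogd
        flags_by_pair[(a, b)] = flags

    scans: dict[str, pd.DataFrame] = {}
    loci: dict[str, list] = {}
    sweep_windows: dict[str, set] = {}
    for p in pops:
        scan = swp.clr_scan(vt, pm, p, ci, grid=cfg.grid,
                            max_window=cfg.max_window)
        scans[p] = scan
        loci[p] = out.call_sweep_loci(scan, cfg.clr_outlier_fraction)
        sweep_windows[p] = out.loci_to_windows(loci[p], windows)

    # association universe: windows with defined FST in every pair
    defined = np.ones(len(windows), dtype=bool)
    for stats in pair_stats.values():
        defined &= stats["fst"].notna().to_numpy()
    universe = list(windows.index[defined])
    remap = {w: i for i, w in enumerate(universe)}
    association: dict[str, res.PermutationResult] = {}
    ogd_union = set().union(*ogd_by_pair.values()) if ogd_by_pair else set()
    for p in pops:
        o = {remap[w] for w in ogd_union if w in remap}
        s = {remap[w] for w in sweep_windows[p] if w in remap}
        association[p] = res.ogd_sweep_association(
            len(universe), o, s, reps=cfg.association_reps,
            seed=seeds["association"])

    enrich: dict[str, dict] = {}
    if genes is not None:
        for p in pops:
            target_windows = ogd_union & sweep_windows[p]
            regions = [
                (windows.loc[w, "chrom"], windows.loc[w, "start"],
                 windows.loc[w, "end"]) for w in sorted(target_windows)
            ]
            target = enr.genes_in_regions(genes, regions)
            fams = sorted(set(genes["family"]))
            fam_res = [enr.family_enrichment(genes, target, f) for f in fams]
            go_res = enr.go_overrepresentation(genes, target, cfg.fdr)
            enrich[p] = {"target_genes": target, "families": fam_res,
                         "go": go_res, "target_windows": target_windows}

    coords, var_frac = pca_quicklook(vt)

    results = {
        "config": asdict(cfg),
        "n_sites": vt.n_sites,
        "n_sites_after_hard_filter": n_after_hard,
        "windows": windows,
        "pair_stats": pair_stats,
        "theta_genome": theta_genome,
        "fst_perm": fst_perm,
        "kendall_tau": tau,
        "ogd_by_pair": ogd_by_pair,
        "flags_by_pair": flags_by_pair,
        "scans": scans,
        "loci": loci,
        "sweep_windows": sweep_windows,
        "association": association,
        "enrichment": enrich,
        "pca": (coords, var_frac),
        "seeds": seeds,
    }
    if write:
        _write_outputs(cfg, results, pm, genes)
    return results


def _write_outputs(cfg: RunConfig, r: dict, pm, genes) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    RunConfig(**r["config"]).to_yaml(outdir / "config.yaml")
    for (a, b), stats in r["pair_stats"].items():
        t = stats.copy()
        t[["fst_outlier", "dxy_outlier", "ogd"]] = r["flags_by_pair"][(a, b)]
        dio.write_stats_table(t, outdir / f"window_stats_{a}_{b}.tsv")
    for p, scan in r["scans"].items():
        dio.write_stats_table(scan, outdir / f"clr_scan_{p}.tsv")
        bed = pd.DataFrame(
            [(l.chrom, int(max(0, l.start)), int(l.end), f"{p}_locus") for l in r["loci"][p]],
            columns=["chrom", "start", "end", "name"],
        )
        dio.write_bed(bed, outdir / f"sweep_loci_{p}.bed", extra_cols=["name"])
    for p, e in r["enrichment"].items():
        dio.write_stats_table(enr.enrichment_table(e["families"]),
                              outdir / f"family_enrichment_{p}.tsv")
        dio.write_stats_table(enr.enrichment_table(e["go"]),
                              outdir / f"go_enrichment_{p}.tsv")
    report = summary_report(r)
    (outdir / "report.txt").write_text(report)
    (outdir / "report.json").write_text(json.dumps(_report_dict(r), indent=2))
    log.info("results written to %s", outdir)


def _report_dict(r: dict) -> dict:
    d = {
        "config": r["config"],
        "seeds": r["seeds"],
        "n_sites": int(r["n_sites"]),
        "pairs": {},
        "populations": {},
        "pca_variance_fractions": [float(v) for v in r["pca"][1]],
    }
    for (a, b) in r["pair_stats"]:
        flags = r["flags_by_pair"][(a, b)]
        d["pairs"][f"{a}-{b}"] = {
            "theta_genome": float(r["theta_genome"][(a, b)]),
            "fst_perm_p": float(r["fst_perm"][(a, b)].p),
            "kendall_tau": float(r["kendall_tau"][(a, b)][0]),
            "kendall_p": float(r["kendall_tau"][(a, b)][1]),
            "n_fst_outliers": int(flags["fst_outlier"].sum()),
            "n_dxy_outliers": int(flags["dxy_outlier"].sum()),
            "n_ogd": int(flags["ogd"].sum()),
        }
    for p in r["scans"]:
        e = r["enrichment"].get(p, {})
        fam = {x.label: x.p for x in e.get("families", [])}
        d["populations"][p] = {
            "n_sweep_loci": len(r["loci"][p]),
            "n_sweep_windows": len(r["sweep_windows"][p]),
            "association_observed": float(r["association"][p].observed),
            "association_p": float(r["association"][p].p),
            "n_target_genes": len(e.get("target_genes", [])),
            "family_p": {k: float(v) for k, v in fam.items()},
            "n_go_significant": len(e.get("go", [])),
        }
    return d


def summary_report(r: dict) -> str:
    d = _report_dict(r)
    lines = [f"divscan run report (seed {r['config']['seed']})",
             f"sites analyzed: {d['n_sites']}", ""]
    for pair, v in d["pairs"].items():
        lines.append(
            f"{pair}: theta={v['theta_genome']:.4f} (perm p={v['fst_perm_p']:.3g}); "
            f"FST outliers={v['n_fst_outliers']}, dXY outliers={v['n_dxy_outliers']}, "
            f"OGD={v['n_ogd']}; dXY-pi tau={v['kendall_tau']:.3f}"
        )
    lines.append("")
    for p, v in d["populations"].items():
        fam = ", ".join(f"{k} p={q:.3g}" for k, q in v["family_p"].items())
        lines.append(
            f"{p}: sweep loci={v['n_sweep_loci']} ({v['n_sweep_windows']} windows); "
            f"OGD-sweep overlap={v['association_observed']:.0f} "
            f"(p={v['association_p']:.3g}); target genes={v['n_target_genes']}; "
            f"{fam}; GO terms FDR<{r['config']['fdr']}: {v['n_go_significant']}"
        )
    pcs = ", ".join(f"PC{i + 1} {100 * f:.1f}%" for i, f in
                    enumerate(d["pca_variance_fractions"]))
    lines.append("")
    lines.append(f"PCA variance: {pcs}")
    return "\n".join(lines) + "\n"
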