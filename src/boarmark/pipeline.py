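"""End-to-end orchestration: simulate -> genotype -> classify -> popgen.

`run` executes the stages requested by a :class:`RunConfig` and writes a
machine-readable JSON report plus CSV side-products.  Identical config
and seeds produce byte-identical CSV outputs; the admixture section is
deterministic per seed.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_mc1r, decide_subspecies, summarize_cohort
from .genotyping import call_all, find_variable_positions, taqman_call
from .markers import extract_amplicon, load_panel
from .popgen import (build_haplotype_table, diplotypes_to_site_coding,
                     evanno_delta_k, fst_weir_cockerham, haplotype_network,
                     network_to_frame, run_admixture_scan)
from .synthetic import CohortSpec, build_backbone, default_cohort_spec, \
    generate_cohort

ALL_STAGES = ("simulate", "genotype", "classify", "popgen")

#: Admixture scale presets: (burn-in, post-burn-in sweeps).
SCALES = {"desk": (2_000, 5_000), "paper": (100_000, 200_000)}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    panel_path: str | None = None        # None -> packaged default panel
    spec_path: str | None = None         # None -> published default cohort
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 1
    out_dir: str = "boarmark_run"
    k_range: tuple[int, int] = (1, 6)
    replicates: int = 10
    scale: str = "desk"

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        if self.scale not in SCALES:
            raise ConfigError(f"unknown scale {self.scale!r}")
        for p in (self.panel_path, self.spec_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"file not found: {p}")


def _panel_checksum(panel_path: str | None) -> str:
    if panel_path is None:
        import importlib.resources
        text = (importlib.resources.files("boarmark.data")
                / "default_panel.yaml").read_text()
    else:
        text = Path(panel_path).read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report dict.

    A stage failure is recorded in the report's ``errors`` section and
    aborts the downstream stages; the partial report is still written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": 1,
        "tool_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "scale": config.scale,
        "panel_checksum": _panel_checksum(config.panel_path),
        "errors": [],
    }
    panel = load_panel(config.panel_path)
    spec = (default_cohort_spec() if config.spec_path in (None, "default")
            else CohortSpec.from_yaml(config.spec_path))

    cohort = None
    diplotypes = nr6a1_calls = verdicts = None
    try:
        if "simulate" in config.stages or {"genotype", "classify",
                                           "popgen"} & set(config.stages):
            backbone = build_backbone(seed=config.seed, panel=panel)
            cohort = generate_cohort(spec, backbone, seed=config.seed)
            cohort.write(out / "cohort")
            report["cohort"] = {
                "n_samples": len(cohort),
                "per_population": {p.name: p.n for p in spec.populations},
                "hybrids": spec.hybrid_count,
            }
    except Exception as err:                      # pragma: no cover
        report["errors"].append({"stage": "simulate", "error": str(err),
                                 "traceback": traceback.format_exc()})

    if cohort is not None and {"genotype", "classify",
                               "popgen"} & set(config.stages):
        try:
            genotypes, nr6a1_calls, amplicons = [], {}, []
            for s in cohort.samples:
                amp = extract_amplicon(s.mc1r_template,
                                       panel.assays["MC1R"].primers, "MC1R")
                amplicons.append(amp)
                genotypes.append(call_all(amp, panel, sample_id=s.sample_id,
                                          breed_label=s.breed))
                nr_amp = extract_amplicon(s.nr6a1_template,
                                          panel.assays["NR6A1"].primers,
                                          "NR6A1")
                nr6a1_calls[s.sample_id] = taqman_call(nr_amp, panel.probes)
            from .genotyping import genotypes_to_frame
            gdf = genotypes_to_frame(genotypes, nr6a1_calls)
            gdf.to_csv(out / "genotypes.csv", index=False)
            wild_amp = extract_amplicon(
                cohort.backbone.mc1r_template,
                panel.assays["MC1R"].primers, "MC1R")
            variable = find_variable_positions(amplicons, wild_amp, panel)
            report["genotyping"] = {
                "n_genotyped": len(genotypes),
                "variable_positions": [
                    {"position": v.position, "segregating": v.segregating,
                     "fixed_difference": v.fixed_difference}
                    for v in variable],
            }
        except Exception as err:
            report["errors"].append({"stage": "genotype", "error": str(err),
                                     "traceback": traceback.format_exc()})
            genotypes = None

        if genotypes is not None and {"classify", "popgen"} & set(config.stages):
            try:
                diplotypes = [classify_mc1r(g) for g in genotypes]
                verdicts = [decide_subspecies(nr6a1_calls[d.sample_id], d)
                            for d in diplotypes]
                dip_tab, ver_tab = summarize_cohort(diplotypes, verdicts)
                dip_tab.to_csv(out / "diplotype_table.csv")
                ver_tab.to_csv(out / "verdict_table.csv")
                pd.DataFrame(
                    [{"sample_id": d.sample_id, "breed": d.breed_label,
                      "diplotype": d.label,
                      "nr6a1": nr6a1_calls[d.sample_id],
                      "verdict": v.verdict, "mc1r_flag": v.mc1r_flag}
                     for d, v in zip(diplotypes, verdicts)]
                ).to_csv(out / "verdicts.csv", index=False)
                report["classification"] = {
                    "diplotype_table": dip_tab.to_dict(),
                    "verdict_table": ver_tab.to_dict(),
                }
            except Exception as err:
                report["errors"].append({"stage": "classify",
                                         "error": str(err),
                                         "traceback": traceback.format_exc()})
                diplotypes = None

        if diplotypes is not None and "popgen" in config.stages:
            try:
                # ground-truth diplotypes (incl. the ED/EP3 split the panel
                # cannot resolve) drive the haplotype table; the classifier
                # output drives everything upstream
                truth_dip = [type("TD", (), {
                    "sample_id": s.sample_id, "breed_label": s.breed,
                    "pair": s.diplotype})() for s in cohort.samples]
                table = build_haplotype_table(truth_dip)
                table.to_frame().to_csv(out / "haplotype_table.csv")
                fst = fst_weir_cockerham(table, "domestic", "wild_boar")
                weights = {c: sum(p.get(c, 0) for p in table.counts.values())
                           for c in table.observed_classes()}
                net = haplotype_network(weights)
                network_to_frame(net).to_csv(out / "network_edges.csv",
                                             index=False)
                burn, reps = SCALES[config.scale]
                x = diplotypes_to_site_coding(truth_dip)
                runs = run_admixture_scan(
                    x, range(config.k_range[0], config.k_range[1] + 1),
                    replicates=config.replicates, seed=config.seed,
                    burn_in=burn, n_reps=reps)
                ev = evanno_delta_k(runs.log_likelihoods())
                ev.table.to_csv(out / "delta_k.csv", index=False)
                if ev.optimal_k is not None:
                    best_fit = runs.fits[ev.optimal_k][0]
                    pd.DataFrame(
                        best_fit.Q,
                        index=[d.sample_id for d in truth_dip],
                        columns=[f"Q{k + 1}" for k in range(ev.optimal_k)],
                    ).to_csv(out / "q_matrix.csv",
                             index_label="sample_id")
                report["popgen"] = {
                    "haplotype_classes": list(table.observed_classes()),
                    "fst": {"theta": fst.theta, "among": fst.among,
                            "within": fst.within,
                            "estimator": fst.estimator},
                    "admixture": {
                        "k_range": list(config.k_range),
                        "replicates": config.replicates,
                        "burn_in": burn, "n_reps": reps,
                        "optimal_k": ev.optimal_k,
                        "delta_k": ev.table.to_dict(orient="list"),
                    },
                }
            except Exception as err:
                report["errors"].append({"stage": "popgen",
                                         "error": str(err),
                                         "traceback": traceback.format_exc()})

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
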