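"""End-to-end orchestration: metrics -> C-S-R -> ANOVA/LMM -> signal ->
PGLS -> Bayesian phylogenetic mixed model, with paper-shaped CSV outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .community import (
    cwm_table,
    group_summaries,
    group_treatment_summary,
    gs_distribution_summary,
    treatment_summary,
)
from .csr import csr_group_table, csr_treatment_summary
from .inference import (
    anova_to_frame,
    four_way_anova,
    per_nutrient_lme,
    two_way_anova,
)
from .pglmm import build_design, gibbs_sampler, summarize
from .pgls import pgls_treatment_means
from .phylo import phylo_covariance
from .records import BiomassTable, RunConfig, SpeciesRecord, SubplotRecord
from .signal import phylo_signal

logger = logging.getLogger("cwm_phylo")

ALL_STAGES = ("metrics", "csr", "anova", "signal", "pgls", "pglmm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class InputBundle:
    species: list[SpeciesRecord]
    design: list[SubplotRecord]
    biomass: BiomassTable
    tree: dendropy.Tree


@dataclass
class PipelineResult:
    cwm: pd.DataFrame
    treatment_summary: pd.DataFrame
    gs_summary: dict
    anova_cwm: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    per_nutrient: pd.DataFrame | None = None
    group_summaries: dict[float, pd.DataFrame] = field(default_factory=dict)
    group_anovas: dict[float, pd.DataFrame] = field(default_factory=dict)
    csr_tables: dict[float, pd.DataFrame] = field(default_factory=dict)
    csr_anovas: dict[float, pd.DataFrame] = field(default_factory=dict)
    signal: dict | None = None
    pgls_means: pd.DataFrame | None = None
    pglmm_summary: pd.DataFrame | None = None
    pglmm_chains: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cwm.to_csv(out / "cwm.csv", index=False)
        self.treatment_summary.to_csv(out / "treatment_summary.csv", index=False)
        if self.anova_cwm is not None:
            self.anova_cwm.to_csv(out / "anova_cwm.csv", index=False)
        if self.contrasts is not None:
            self.contrasts.to_csv(out / "treatment_contrasts.csv", index=False)
        if self.per_nutrient is not None:
            self.per_nutrient.to_csv(out / "per_nutrient_lme.csv", index=False)
        for thr, df in self.group_summaries.items():
            df.to_csv(out / f"group_summary_thr{thr:g}.csv", index=False)
        for thr, df in self.group_anovas.items():
            df.to_csv(out / f"group_anova_thr{thr:g}.csv", index=False)
        for thr, df in self.csr_tables.items():
            df.to_csv(out / f"csr_thr{thr:g}.csv", index=False)
        for thr, df in self.csr_anovas.items():
            df.to_csv(out / f"csr_anova_thr{thr:g}.csv", index=False)
        if self.signal is not None:
            pd.DataFrame([self.signal]).to_csv(out / "signal.csv", index=False)
        if self.pgls_means is not None:
            self.pgls_means.to_csv(out / "pgls_treatment_means.csv", index=False)
        if self.pglmm_summary is not None:
            self.pglmm_summary.to_csv(out / "pglmm_summary.csv", index=False)
        if self.pglmm_chains is not None:
            self.pglmm_chains.to_csv(out / "pglmm_chains.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        (out / "report.md").write_text(self._render_report())

    def _render_report(self) -> str:
        lines = ["# Community genome-size analysis report", ""]
        lines += ["## Genome-size distribution", "", f"```\n{json.dumps(self.gs_summary, indent=2)}\n```", ""]
        lines += ["## Treatment summary", "", self.treatment_summary.to_string(index=False), ""]
        if self.anova_cwm is not None:
            lines += ["## Two-way ANOVA of CWM genome size", "", self.anova_cwm.to_string(index=False), ""]
        if self.signal is not None:
            lines += ["## Phylogenetic signal in genome size", "", f"```\n{json.dumps(self.signal, indent=2)}\n```", ""]
        if self.pglmm_summary is not None:
            lines += ["## Phylogenetic mixed model posterior summary", "", self.pglmm_summary.to_string(index=False), ""]
        lines += ["", f"_seed: {self.provenance.get('seed')}, version: {self.provenance.get('version')}_"]
        return "\n".join(lines)


def run_pipeline(
    inputs: InputBundle,
    config: RunConfig | None = None,
    thresholds: Sequence[float] | None = None,
    stages: Sequence[str] | None = None,
) -> PipelineResult:
    """Run the full analysis; any stage failure aborts naming the stage.

    ``thresholds`` defaults to the configured genome-size threshold;
    pass ``(2.5, 3, 5, 6)`` for the full sweep.  ``stages`` restricts
    execution (metrics always runs); disabling a stage leaves every
    other stage's output unchanged.
    """
    config = config or RunConfig()
    thresholds = list(thresholds or [config.gs_threshold_pg])
    enabled = set(stages or ALL_STAGES)
    result = _run(inputs, config, thresholds, enabled)
    return result


def _run(inputs, config, thresholds, enabled) -> PipelineResult:
    stage = "metrics"
    try:
        cwm = cwm_table(
            inputs.biomass, inputs.species, inputs.design,
            drop_missing_gs=config.drop_missing_gs,
        )
        res = PipelineResult(
            cwm=cwm,
            treatment_summary=treatment_summary(cwm),
            gs_summary=gs_distribution_summary(inputs.species),
        )
        for thr in thresholds:
            res.group_summaries[thr] = group_summaries(
                inputs.biomass, inputs.species, inputs.design, threshold_pg=thr
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if "csr" in enabled:
        stage = "csr"
        try:
            for thr in thresholds:
                res.csr_tables[thr] = csr_group_table(
                    inputs.biomass, inputs.species, inputs.design, threshold_pg=thr
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if "anova" in enabled:
        stage = "anova"
        try:
            table, contrasts = two_way_anova(res.cwm)
            res.anova_cwm = anova_to_frame(table)
            res.contrasts = contrasts
            _, sig = per_nutrient_lme(res.cwm, inputs.design)
            res.per_nutrient = sig
            for thr in thresholds:
                res.group_anovas[thr] = anova_to_frame(
                    four_way_anova(res.group_summaries[thr])
                )
                if thr in res.csr_tables:
                    res.csr_anovas[thr] = _csr_anova(res.csr_tables[thr])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    cov = None
    if {"signal", "pgls", "pglmm"} & enabled:
        cov = phylo_covariance(inputs.tree)

    if "signal" in enabled:
        stage = "signal"
        try:
            labels = [s.species_id for s in inputs.species if s.species_id in cov.tip_labels]
            sub = cov.subset(labels)
            smap = {s.species_id: s for s in inputs.species}
            vals = np.array([smap[l].one_c_pg for l in labels])
            trait = np.log(vals) if config.signal_log_scale else vals
            sig = phylo_signal(trait, sub, n_perm=config.n_permutations, seed=config.seed)
            res.signal = {
                "k_stat": sig.k_stat,
                "k_pvalue": sig.k_pvalue,
                "lambda_hat": sig.lambda_hat,
                "lambda_loglik": sig.lambda_loglik,
                "lambda_lr_pvalue": sig.lambda_lr_pvalue,
                "scale": "log 1C" if config.signal_log_scale else "1C (pg)",
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if "pgls" in enabled:
        stage = "pgls"
        try:
            by_treat = _biomass_by_treatment(inputs)
            smap = {s.species_id: s for s in inputs.species}
            trait = {sid: float(np.log(smap[sid].one_c_pg)) for sid in by_treat.index}
            res.pgls_means = pgls_treatment_means(trait, cov, by_treat)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if "pglmm" in enabled:
        stage = "pglmm"
        try:
            design = build_design(inputs.biomass, inputs.species, inputs.design, inputs.tree)
            chains = gibbs_sampler(design, config.prior, config.mcmc, seed=config.seed)
            res.pglmm_chains = chains
            res.pglmm_summary = summarize(chains)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    res.provenance = {
        "seed": config.seed,
        "gs_thresholds": thresholds,
        "stages": sorted(enabled),
        "mcmc": {
            "iterations": config.mcmc.iterations,
            "burn_in": config.mcmc.burn_in,
            "thinning": config.mcmc.thinning,
        },
        "prior": {"v": config.prior.v, "nu": config.prior.nu},
        "n_permutations": config.n_permutations,
        "version": __version__,
    }
    return res


def _csr_anova(csr_df: pd.DataFrame) -> pd.DataFrame:
    """Four-way ANOVA per strategy on square-root partitioned biomass."""
    frames = []
    for strategy, col in (("C", "c_g"), ("S", "s_g"), ("R", "r_g")):
        df = csr_df[["subplot_id", "treatment", "group"]].copy()
        df["sqrt_biomass"] = np.sqrt(csr_df[col].to_numpy(float))
        tab = anova_to_frame(four_way_anova(df))
        tab.insert(0, "strategy", strategy)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _biomass_by_treatment(inputs: InputBundle) -> pd.DataFrame:
    from .community import classify_treatment
    from .records import design_map

    dmap = design_map(inputs.design)
    cols = {}
    for sub_id in inputs.biomass.subplot_ids:
        t = classify_treatment(dmap[sub_id])
        cols.setdefault(t, []).append(sub_id)
    out = {}
    for t, subs in cols.items():
        out[t] = inputs.biomass.data[subs].sum(axis=1)
    return pd.DataFrame(out)
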