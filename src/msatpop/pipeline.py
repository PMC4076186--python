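"""End-to-end orchestration of the full analysis workflow.

The pipeline mirrors the comparative with/without-null-correction design:
ingest (or simulate) → diversity/HWE/LD → null-allele estimation →
corrected dataset → relatedness classification and dyad frequencies
(both modes) → kin permutation tests → paired t comparisons → sibship
networks → F-statistics (raw + ENA).  Every stochastic stage draws its
own seed from one root seed, so an identical configuration yields an
identical report bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import diversity, io, kintests, nulls, relatedness, sibship, structure
from .data import GenotypeDataset, allele_frequencies
from .simulate import SimulationConfig, generate_study_like_dataset, simulate_dataset

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("msatpop")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one full run.

    ``source`` is a GenePop/CSV path, a :class:`SimulationConfig`, or the
    string ``"study-like"``.  ``mode`` selects which datasets flow into
    the downstream analyses: ``raw``, ``corrected`` or ``both``.
    """

    source: Union[str, SimulationConfig] = "study-like"
    outdir: Optional[str] = None
    seed: int = 0
    mode: str = "both"
    hwe_steps: int = 1000
    hwe_dememorization: int = 10000
    ld_iterations: int = 499
    fis_randomizations: int = 200
    kin_permutations: int = 1000
    fst_permutations: int = 999
    bootstrap_iterations: int = 50000
    min_confidence: float = 0.95
    run_ld: bool = True
    run_kin: bool = True
    run_fst: bool = True
    allele_digits: int = 3

    def validate(self) -> None:
        for name in (
            "hwe_steps", "ld_iterations", "kin_permutations",
            "fst_permutations", "bootstrap_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mode not in ("raw", "corrected", "both"):
            raise ValueError("mode must be raw, corrected or both")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.source = SimulationConfig(**sim)
        return cfg


def _ingest(config: RunConfig):
    if isinstance(config.source, SimulationConfig):
        return simulate_dataset(config.source)
    if config.source == "study-like":
        return generate_study_like_dataset(config.seed)
    path = str(config.source)
    if path.endswith(".csv"):
        return io.read_csv(path), None
    return io.read_genepop(path, config.allele_digits), None


def _write(outdir: Optional[Path], name: str, content) -> None:
    if outdir is None:
        return
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if isinstance(content, pd.DataFrame):
        content.to_csv(path, sep="\t", index=True)
    else:
        path.write_text(content)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole workflow; returns (and optionally writes) the
    report bundle as a dict of tables and headline numbers."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    ss = np.random.SeedSequence(config.seed)

    def next_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    bundle: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed}
    ds, truth = _ingest(config)
    log.info("dataset: %d individuals, %d loci, %d populations",
             len(ds.individuals), len(ds.loci), len(ds.pop_order))
    if truth is not None and outdir is not None:
        _write(outdir, "truth.json", truth.to_json())

    # --- diversity / HWE -------------------------------------------------
    summary = diversity.locus_summary(
        ds, config.hwe_steps, config.hwe_dememorization, next_seed()
    )
    glob_hwe = diversity.global_hwe(summary)
    _write(outdir, "table3_diversity.tsv", summary)
    _write(outdir, "global_hwe.tsv", glob_hwe)
    bundle["diversity"] = summary
    bundle["global_hwe"] = glob_hwe

    # --- linkage disequilibrium ------------------------------------------
    if config.run_ld:
        rng_seed = next_seed()
        ld_ss = np.random.SeedSequence(rng_seed)
        rows = []
        for pop in ds.pop_order:
            for i in range(len(ds.loci)):
                for j in range(i + 1, len(ds.loci)):
                    try:
                        p = diversity.ld_genotypic_test(
                            ds, ds.loci[i], ds.loci[j], pop,
                            config.ld_iterations,
                            np.random.default_rng(ld_ss.spawn(1)[0]),
                        )
                    except ValueError:
                        p = float("nan")
                    rows.append({"population": pop, "locus_a": ds.loci[i],
                                 "locus_b": ds.loci[j], "p": p})
        ld = pd.DataFrame(rows)
        k_tests = len(ds.loci) * (len(ds.loci) - 1) // 2
        ld_alpha = diversity.bonferroni_threshold(0.05, k_tests)
        ld["significant"] = ld["p"] < ld_alpha
        _write(outdir, "ld_tests.tsv", ld)
        bundle["ld"] = ld
        bundle["ld_bonferroni_alpha"] = ld_alpha

    # --- null alleles and corrected dataset -------------------------------
    null_est = nulls.estimate_nulls(ds, seed=next_seed())
    _write(outdir, "null_estimates.tsv", null_est.to_frame())
    bundle["null_estimates"] = null_est.to_frame()
    ds_corr = nulls.adjust_genotypes(ds, null_est)

    # --- F_IS (raw and corrected) -----------------------------------------
    fis_raw = diversity.fis_weir_cockerham(
        ds, randomizations=config.fis_randomizations, seed=next_seed()
    )
    bundle["fis_raw"] = fis_raw
    frames = [fis_raw.to_frame().assign(dataset="uncorrected")]
    if config.mode in ("corrected", "both"):
        fis_corr = diversity.fis_weir_cockerham(
            ds_corr, randomizations=config.fis_randomizations, seed=next_seed()
        )
        bundle["fis_corrected"] = fis_corr
        frames.append(fis_corr.to_frame().assign(dataset="corrected"))
    _write(outdir, "table4_fis.tsv", pd.concat(frames, ignore_index=True))

    # --- relatedness classification and dyad frequencies -------------------
    freqs_raw = allele_frequencies(ds)
    freqs_null = null_est.em_table(only_flagged=True)
    dyad_freqs = relatedness.dyad_frequency_table(ds, freqs_raw, freqs_null)
    _write(outdir, "table6_dyad_frequencies.tsv", dyad_freqs)
    bundle["dyad_frequencies"] = dyad_freqs
    t_hs = kintests.paired_t_test(dyad_freqs["HS_NNA"], dyad_freqs["HS_NA"])
    t_fs = kintests.paired_t_test(dyad_freqs["FS_NNA"], dyad_freqs["FS_NA"])
    bundle["dyad_ttest"] = {"HS": t_hs, "FS": t_fs}

    # --- kin aggregation permutation tests ---------------------------------
    if config.run_kin:
        kin = kintests.relatedness_permutation_test(
            ds, config.kin_permutations, next_seed()
        )
        _write(outdir, "table5_kin_p_raw.tsv", kin.p)
        bundle["kin_raw"] = kin
        if config.mode in ("corrected", "both"):
            pooled = GenotypeDataset(
                ds.individuals, {i: "ALL" for i in ds.individuals},
                ds.loci, ds.calls,
            )
            pooled_nulls = nulls.estimate_nulls(pooled, seed=next_seed())
            kin_na = kintests.relatedness_permutation_test(
                ds, config.kin_permutations, next_seed(),
                freq_table=pooled_nulls.em_table(only_flagged=True),
            )
            _write(outdir, "table5_kin_p_nulls.tsv", kin_na.p)
            bundle["kin_nulls"] = kin_na

    # --- sibship networks ---------------------------------------------------
    dyads = relatedness.classify_dyads(ds, freqs_raw)
    reports = []
    for pop in ds.pop_order:
        edges = sibship.build_sibship_graph(dyads, pop, config.min_confidence)
        part = sibship.extended_networks(edges, ds.individuals_in(pop))
        reports.append(f"== {pop} ==\n" + sibship.network_report(part))
    _write(outdir, "sibship_networks.txt", "\n".join(reports))
    bundle["sibship_report"] = "\n".join(reports)

    # --- population structure ----------------------------------------------
    if config.run_fst and len(ds.pop_order) >= 2:
        fst = structure.pairwise_fst(
            ds, config.fst_permutations, next_seed(),
            config.bootstrap_iterations,
            global_p_iterations=config.fst_permutations,
        )
        _write(outdir, "table7_fst.tsv", fst.display())
        bundle["fst"] = fst
        ena_theta, ena_comps = structure.ena_corrected_theta(
            ds, null_est, return_components=True
        )
        bundle["fst_ena_global"] = ena_theta
        _, raw_comps = structure.wc_theta(ds, return_components=True)
        raw_pl, ena_pl = [], []
        for locus in ds.loci:
            ra = raw_comps[locus]
            ea = ena_comps[locus]
            rt, et = sum(ra), sum(ea)
            if rt != 0 and et != 0:
                raw_pl.append(ra[0] / rt)
                ena_pl.append(ea[0] / et)
        if len(raw_pl) >= 2:
            bundle["fst_ena_ttest"] = kintests.paired_t_test(raw_pl, ena_pl)
        k_pairs = len(ds.pop_order) * (len(ds.pop_order) - 1) // 2
        bundle["fst_bonferroni_alpha"] = diversity.bonferroni_threshold(0.05, k_pairs)

    # --- machine-readable summary -------------------------------------------
    summary_json = _bundle_summary(bundle)
    if outdir is not None:
        _write(outdir, "summary.json", json.dumps(summary_json, indent=2))
    bundle["summary"] = summary_json
    return bundle


def _bundle_summary(bundle: dict) -> dict:
    out: dict = {"schema_version": bundle["schema_version"], "seed": bundle["seed"]}
    if "fis_raw" in bundle:
        out["fis_overall_raw"] = bundle["fis_raw"].overall
        out["fis_p_raw"] = bundle["fis_raw"].p
    if "fis_corrected" in bundle:
        out["fis_overall_corrected"] = bundle["fis_corrected"].overall
    if "dyad_ttest" in bundle:
        out["dyad_ttest_hs_p"] = bundle["dyad_ttest"]["HS"][2]
        out["dyad_ttest_fs_p"] = bundle["dyad_ttest"]["FS"][2]
    if "fst" in bundle:
        fst = bundle["fst"]
        out["fst_global"] = fst.global_theta
        out["fst_global_ci"] = list(fst.global_ci) if fst.global_ci else None
        out["fst_global_p"] = fst.global_p
    if "fst_ena_global" in bundle:
        out["fst_ena_global"] = bundle["fst_ena_global"]
    if "fst_bonferroni_alpha" in bundle:
        out["fst_bonferroni_alpha"] = bundle["fst_bonferroni_alpha"]
    if "kin_raw" in bundle:
        diag = np.diag(bundle["kin_raw"].p.to_numpy())
        out["kin_intra_significant"] = int(np.nansum(diag < 0.05))
    return out
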