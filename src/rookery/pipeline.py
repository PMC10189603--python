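"""End-to-end orchestration: simulate -> qc -> relatedness -> kin ->
parentage -> popgen -> spatial -> report.

Every stage writes its outputs before the next starts, a manifest records
seeds, thresholds and filter chains, and the whole run is deterministic
under a fixed seed (per-stage seeds are spawned from the master seed; no
global random state is touched).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinlik, pedigree, popgen, qc, relatedness, spatial
from .config import PipelineConfig
from .simulate import ErrorModel, RookeryDesign, simulate_rookery

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "relatedness", "kin", "parentage", "popgen", "spatial")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages in fixed order; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _spawn_seeds(config.seed, len(STAGES))))
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, paths: list[Path]):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    state: dict = {}
    try:
        stage = "simulate"
        if config.run_simulate:
            design = RookeryDesign(
                n_females=config.n_females,
                n_males=config.n_males,
                polygyny_pairs=config.polygyny_pairs,
            )
            error = ErrorModel(
                config.dropout_rate,
                config.other_error_rate,
                config.missing_rate,
                config.likelihood_error,
            )
            rk = simulate_rookery(
                design,
                n_loci=config.n_loci,
                fst=config.fst,
                error=error,
                seed=seeds[stage],
                depth_mean_range=(config.depth_mean_low, config.depth_mean_high),
                view_noise=config.view_noise,
                replicate_fraction=config.replicate_fraction,
            )
            state["rookery"] = rk
            paths = []
            p = out / "truth_genotypes.tsv"; rk.truth.write_tsv(p); paths.append(p)
            p = out / "observed_genotypes.tsv"; rk.bundle.observed.write_tsv(p); paths.append(p)
            p = out / "depths.csv"; rk.bundle.depths.write_csv(p); paths.append(p)
            p = out / "panel_freqs.tsv"; rk.panel.write_tsv(p); paths.append(p)
            rk.pedigree.write(out / "pedigree")
            paths += sorted(out.glob("pedigree.*.tsv"))
            for i, view in enumerate(rk.bundle.caller_views):
                p = out / f"caller_{i + 1}.tsv"; view.write_tsv(p); paths.append(p)
            p = out / "replicates.tsv"
            pd.DataFrame(rk.bundle.replicate_pairs, columns=["original", "replicate"]).to_csv(
                p, sep="\t", index=False
            )
            paths.append(p)
            record(stage, paths)

        stage = "qc"
        if config.run_qc and "rookery" in state:
            rk = state["rookery"]
            res = qc.run_qc(
                rk.bundle.depths,
                rk.bundle.caller_views,
                rk.bundle.replicate_pairs,
                min_total_reads=config.min_total_reads,
                min_depth=config.min_depth,
                hom_max=config.hom_max_ratio,
                het_min=config.het_min_ratio,
                min_ratio_fraction=config.min_ratio_fraction,
                min_callers=config.min_callers,
                max_caller_mismatch=config.max_caller_mismatch,
                max_replicate_mismatch=config.max_replicate_mismatch,
                min_maf=config.min_maf,
                missing_start=config.missing_start,
                missing_end=config.missing_end,
                min_consistency=config.min_consistency,
            )
            state["qc_table"] = res.table
            p1 = out / "qc_genotypes.tsv"; res.table.write_tsv(p1)
            p2 = out / "qc_filter_report.tsv"; res.report.write_tsv(p2)
            record(stage, [p1, p2])

        table = state.get("qc_table")
        if table is not None:
            # drop replicate rows for the analysis stages
            primary = [s for s in table.individuals if "__rep" not in s]
            analysis = table.subset(individuals=primary)
            ref = relatedness.ReferenceFreqs.from_table(analysis)
            state["analysis"] = analysis
            state["ref"] = ref

        stage = "relatedness"
        if config.run_relatedness and "analysis" in state:
            analysis, ref = state["analysis"], state["ref"]
            rk = state["rookery"]
            adults = [a for a in rk.pedigree.adult_ids if a in analysis._ind_index]
            pairs = [(adults[i], adults[j]) for i in range(len(adults)) for j in range(i + 1, len(adults))]
            df = relatedness.pairwise_r(analysis, ref, pairs)
            p1 = out / "relatedness_adults.tsv"; df.to_csv(p1, sep="\t", index=False)
            edges = relatedness.relatedness_edge_list(df)
            p2 = out / "relatedness_edges.tsv"; edges.to_csv(p2, sep="\t", index=False)
            state["adult_r"] = df
            record(stage, [p1, p2])

        stage = "kin"
        if config.run_kin and "analysis" in state:
            ref = state["ref"]
            calib = kinlik.mc_calibrate(
                ref.freqs, n=config.n_sim_pairs, e=config.likelihood_error, seed=seeds[stage]
            )
            p = out / "kin_calibration.tsv"; calib.summary.to_csv(p, sep="\t", index=False)
            record(stage, [p])

        stage = "parentage"
        if config.run_parentage and "analysis" in state:
            analysis, ref = state["analysis"], state["ref"]
            rk = state["rookery"]
            nests = [
                pedigree.NestRecord(
                    row.nest_id,
                    row.beach,
                    row.complex,
                    [o for o in rk.pedigree.offspring.loc[
                        rk.pedigree.offspring["nest"] == row.nest_id, "id"
                    ] if o in analysis._ind_index],
                    observed_mother=row.mother_id,
                )
                for row in rk.pedigree.nests.itertuples(index=False)
                if any(o in analysis._ind_index for o in rk.pedigree.offspring.loc[
                    rk.pedigree.offspring["nest"] == row.nest_id, "id"
                ])
            ]
            mother_of_nest = {n.nest_id: n.observed_mother for n in nests}
            fathers = pedigree.reconstruct_fathers_by_mother(
                analysis, nests, mother_of_nest, ref.freqs, e=config.likelihood_error,
                seed=seeds[stage],
            )
            sib = pedigree.confirm_sib_structure(
                nests, analysis, ref.freqs, e=config.likelihood_error,
                max_pairs_within=10, max_pairs_cross=6, seed=seeds[stage],
            )
            mating = pedigree.detect_polygyny(fathers, sib.cross)
            offspring = [o for o in rk.pedigree.offspring_ids if o in analysis._ind_index]
            ne = pedigree.sibship_ne(
                offspring, analysis, ref.freqs, e=config.likelihood_error,
                max_pairs=400, n_boot=50, seed=seeds[stage],
            )
            rows = []
            for f in fathers:
                rows.append({"father": f.father_id, "mother": f.mother_id,
                             "masked_fraction": f.masked_fraction()})
            p1 = out / "fathers.tsv"; pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
            p2 = out / "mating_map.tsv"
            pd.DataFrame(
                [(f, ";".join(ms)) for f, ms in mating.father_to_mothers.items()],
                columns=["father", "mothers"],
            ).to_csv(p2, sep="\t", index=False)
            p3 = out / "ne.tsv"
            pd.DataFrame([dataclasses.asdict(x) for x in ne]).to_csv(p3, sep="\t", index=False)
            p4 = out / "nesting_summary.tsv"
            pedigree.summarize_nesting(rk.pedigree.nests).to_csv(p4, sep="\t", index=False)
            record(stage, [p1, p2, p3, p4])

        stage = "popgen"
        if config.run_popgen and "analysis" in state:
            analysis = state["analysis"]
            rk = state["rookery"]
            cx = rk.pedigree.complex_of()
            adults = [a for a in rk.pedigree.adult_ids if a in analysis._ind_index]
            groups = {a: cx[a] for a in adults}
            atab = analysis.subset(individuals=adults)
            diff = popgen.differentiation(atab, groups, n_perm=config.n_perm, seed=seeds[stage])
            p1 = out / "differentiation.tsv"; diff.per_locus.to_csv(p1, sep="\t")
            p2 = out / "differentiation_overall.tsv"
            pd.DataFrame([{**diff.overall, **{f"p_{k}": v for k, v in diff.p_values.items()}}]).to_csv(
                p2, sep="\t", index=False
            )
            record(stage, [p1, p2])

        stage = "spatial"
        if config.run_spatial and "analysis" in state:
            analysis = state["analysis"]
            rk = state["rookery"]
            females = [f for f in rk.pedigree.females["id"] if f in analysis._ind_index]
            coords = rk.pedigree.females.set_index("id").loc[females, ["lon", "lat"]]
            ftab = analysis.subset(individuals=females)
            sp = spatial.spca_rtest(
                ftab, coords.reset_index().rename(columns={"id": "individual"}),
                k_neighbors=config.k_neighbors, n_perm=config.n_perm, seed=seeds[stage],
            )
            p1 = out / "spca_scores.tsv"; sp.scores.to_csv(p1, sep="\t")
            p2 = out / "spca_summary.tsv"
            pd.DataFrame(
                [{"global_stat": sp.global_stat, "p": sp.p_value, "n_perm": sp.n_perm}]
            ).to_csv(p2, sep="\t", index=False)
            record(stage, [p1, p2])
    except Exception as exc:  # noqa: BLE001 - re-raise with stage scope
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
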