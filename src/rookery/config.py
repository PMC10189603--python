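"""Pipeline configuration: a flat key-value text format.

Every tunable threshold of the pipeline lives here with its default equal
to the study value (sample read minimum 10 000, replicate mismatch 7%,
caller mismatch 5.5%, MAF 1%, missingness 80->30%, depth 12, allelic
ratios 0.09/0.20, acceptable-ratio fraction 0.7, consistency 93%,
per-locus likelihood error 2%, 1000 bootstrap/permutation replicates).
Unknown keys are rejected; configs round-trip losslessly.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path


@dataclasses.dataclass
class PipelineConfig:
    # stage toggles
    run_simulate: bool = True
    run_qc: bool = True
    run_relatedness: bool = True
    run_kin: bool = True
    run_parentage: bool = True
    run_popgen: bool = True
    run_spatial: bool = True

    seed: int = 0

    # synthetic rookery
    n_loci: int = 135
    fst: float = 0.04
    n_females: int = 13
    n_males: int = 12
    polygyny_pairs: int = 1
    dropout_rate: float = 0.035
    other_error_rate: float = 0.004
    missing_rate: float = 0.005
    replicate_fraction: float = 0.12
    view_noise: float = 0.02
    depth_mean_low: float = 300.0
    depth_mean_high: float = 500.0

    # QC thresholds
    min_total_reads: int = 10_000
    min_depth: int = 12
    hom_max_ratio: float = 0.09
    het_min_ratio: float = 0.20
    min_ratio_fraction: float = 0.7
    min_callers: int = 2
    max_caller_mismatch: float = 0.055
    max_replicate_mismatch: float = 0.07
    min_maf: float = 0.01
    missing_start: float = 0.80
    missing_end: float = 0.30
    min_consistency: float = 0.93

    # relatedness / kin
    n_boot: int = 1000
    min_cotyped_loci: int = 20
    likelihood_error: float = 0.02
    n_sim_pairs: int = 1000

    # popgen / spatial
    n_perm: int = 200
    n_pc: int = 20
    k_neighbors: int = 5

    def write(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            ftype = known[key].type
            if ftype in ("bool", bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif ftype in ("int", int):
                kwargs[key] = int(val)
            elif ftype in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)
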