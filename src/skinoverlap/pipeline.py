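"""End-to-end orchestration: data → filters → statistics → report bundle.

A run is fully described by a :class:`RunConfig`; the output bundle is a
directory of deterministic CSVs plus the resolved config, a structured
log and a checksum manifest, so identical config + seed reproduces a
byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .dataset import DEFAULT_EXCLUDED_SITES, SkinDataset, filter_sites, read_dataset, write_outputs
from .gamut import gamut_overlap_matrix, gamut_volumes
from .individual import ThresholdConfig, individual_overlap_matrix
from .intragroup import anova_two_way, summarize_groups
from .matrices import OverlapMatrix
from .robust import MatrixAgreement, bootstrap_median_ci, matrix_correlation

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]


@dataclass
class RunConfig:
    """Everything a full analysis run depends on."""

    scenario: str | None = "issa_like"  # generator preset, or None to read input_path
    input_path: str | None = None
    input_format: str = "lab_csv"
    illuminant: str = "D65"
    observer: str = "1964_10deg"
    excluded_sites: tuple[str, ...] = DEFAULT_EXCLUDED_SITES
    pt: float = 2.0
    voxel_edge: float = 3.0
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 42
    out_dir: str = "results"
    run_anova: bool = True

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_path is None):
            raise ValueError("exactly one of scenario / input_path must be set")


@dataclass
class ReportBundle:
    out_dir: Path
    summary: pd.DataFrame
    individual: OverlapMatrix
    gamut: OverlapMatrix
    medians: pd.DataFrame
    agreement: pd.DataFrame
    volumes: pd.Series
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)


def _load(config: RunConfig, log: list[str]) -> SkinDataset:
    if config.scenario is not None:
        presets = synthetic.preset_scenarios(seed=config.seed)
        if config.scenario not in presets:
            raise ValueError(
                f"unknown scenario {config.scenario!r}; available: {sorted(presets)}"
            )
        ds = synthetic.generate_dataset(presets[config.scenario])
        log.append(f"load: generated scenario={config.scenario} seed={config.seed} "
                   f"n={len(ds)} groups={len(ds.groups)}")
    else:
        ds = read_dataset(
            config.input_path,
            format=config.input_format,
            illuminant=config.illuminant,
            observer=config.observer,
        )
        log.append(f"load: read {config.input_path} n={len(ds)} groups={len(ds.groups)}")
    return ds


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    log: list[str] = []
    ds = _load(config, log)
    ds = filter_sites(ds, config.excluded_sites, log=log)
    log.append(f"filter: n={len(ds)}")

    summary = summarize_groups(ds)
    log.append(f"summarize: groups={len(summary)}")

    anova_tables: dict[str, pd.DataFrame] = {}
    if config.run_anova:
        for attr in ("L", "a", "b"):
            anova_tables[attr] = anova_two_way(ds, attribute=attr)
        log.append("anova: attributes=L,a,b type=2")

    threshold = ThresholdConfig(config.pt)
    ind = individual_overlap_matrix(ds, threshold)
    log.append(f"overlap-individual: cells={ind.values.size} pt={config.pt}")

    gam = gamut_overlap_matrix(ds, edge=config.voxel_edge)
    vols = gamut_volumes(ds, edge=config.voxel_edge)
    log.append(f"overlap-gamut: cells={gam.values.size} edge={config.voxel_edge} "
               f"total_cubes={int(vols.sum())}")

    med_rows = []
    for name, matrix in (("individual", ind), ("gamut", gam)):
        ci = bootstrap_median_ci(
            matrix.off_diagonal(), n_boot=config.n_boot, level=config.ci_level,
            seed=config.seed,
        )
        med_rows.append(
            {"method": name, "median": ci.median, "ci_low": ci.ci_low,
             "ci_high": ci.ci_high, "level": ci.level, "n_boot": ci.n_boot,
             "seed": config.seed}
        )
    medians = pd.DataFrame(med_rows).set_index("method")
    log.append(f"bootstrap: n_boot={config.n_boot} level={config.ci_level}")

    if ind.n_groups >= 3:
        agree = matrix_correlation(ind, gam)
    else:  # two groups → two off-diagonal cells, correlation undefined
        agree = MatrixAgreement(r=float("nan"), p=float("nan"),
                                n_cells=ind.off_diagonal().size, defined=False)
    agreement = pd.DataFrame(
        [
            {
                "r": agree.r if agree.defined else "",
                "p": agree.p if agree.defined else "",
                "n_cells": agree.n_cells,
                "defined": agree.defined,
            }
        ]
    )
    log.append(
        "agreement: " + (f"r={agree.r:.4f} p={agree.p:.3g}" if agree.defined
                         else "undefined (zero off-diagonal variance)")
    )

    out = Path(config.out_dir)
    tables = {
        "group_summary": summary,
        "overlap_individual": ind.to_dataframe().rename_axis("reference"),
        "overlap_gamut": gam.to_dataframe().rename_axis("reference"),
        "gamut_volumes": vols.rename_axis("group").to_frame(),
        "median_ci": medians,
        "matrix_agreement": agreement,
    }
    for attr, tbl in anova_tables.items():
        tables[f"anova_{attr}"] = tbl
    paths = write_outputs(tables, out)

    cfg_path = out / "run_config.json"
    cfg = asdict(config)
    cfg["excluded_sites"] = list(cfg["excluded_sites"])
    cfg["out_dir"] = str(cfg["out_dir"])
    cfg["input_path"] = None if cfg["input_path"] is None else str(cfg["input_path"])
    cfg_path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    log_path = out / "run.log"
    log_path.write_text("\n".join(log) + "\n")

    manifest = {}
    for p in sorted(paths + [cfg_path, log_path]):
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.txt").write_text(
        "".join(f"{digest}  {name}\n" for name, digest in manifest.items())
    )

    return ReportBundle(
        out_dir=out,
        summary=summary,
        individual=ind,
        gamut=gam,
        medians=medians,
        agreement=agreement,
        volumes=vols,
        anova=anova_tables,
        manifest=manifest,
    )
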