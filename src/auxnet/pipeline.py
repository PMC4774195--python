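"""End-to-end orchestration: parse -> filter -> binarize -> standardize ->
model scans -> diagnostics -> reports.

``run_pipeline`` consumes a :class:`PipelineConfig`, runs every requested
model family (Bernoulli on the binary network; Gaussian and regression
families on the valued network) over a range of cluster counts, selects
each family's best model by ICL, and writes a deterministic report
bundle: networks, scan tables, best-fit parameters, cluster membership
tables sorted by centrality, the pairwise partition-match matrix and a
run manifest.  Re-running with the same config and seed reproduces every
numeric output byte-identically.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binarize import build_binary_network
from .blockmodel import model_scan
from .covariates import align_covariates, read_phylip_square
from .quality import cluster_distance_matrix, membership_table, partition_match, \
    profile_distance_matrix
from .standardize import standardized_distance_matrix, weight_presets
from .y2h import OrdinalScale, Roster, filter_regulators, parse_y2h_table

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_VALUED_FAMILIES = {"gaussian", "gaussian_regression"}


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run.

    ``covariate_paths`` maps covariate names (e.g. ``DIII``) to PHYLIP
    square matrix files; the regression family uses them all.  The
    config-file format is flat ``key = value`` text; CLI flags override
    config keys and the manifest freezes the resolved values.
    """

    y2h_path: str = ""
    covariate_paths: dict[str, str] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)
    xgal_threshold: str = "+"
    his3_threshold: float = 0.45
    weight_preset: str = "A"
    families: list[str] = field(default_factory=lambda: ["bernoulli", "gaussian"])
    q_min: int = 1
    q_max: int = 6
    n_restarts: int = 10
    seed: int = 0
    outdir: str = "auxnet-out"

    def validate(self) -> None:
        if self.q_min < 1 or self.q_max < self.q_min:
            raise ValueError("Q range must be non-empty with q_min >= 1")
        if not Path(self.y2h_path).exists():
            raise FileNotFoundError(self.y2h_path)
        for name, p in self.covariate_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"covariate {name}: {p}")
        if self.weight_preset not in weight_presets():
            raise ValueError(f"unknown weight preset {self.weight_preset!r}")


_LIST_KEYS = {"exclusions", "families"}
_INT_KEYS = {"q_min", "q_max", "n_restarts", "seed"}
_FLOAT_KEYS = {"his3_threshold"}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file.

    Lists are comma-separated; covariates are given as
    ``covariate.<NAME> = <path>`` lines.
    """
    cfg = PipelineConfig()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {line_no}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("covariate."):
            cfg.covariate_paths[key.split(".", 1)[1]] = value
        elif key in _LIST_KEYS:
            setattr(cfg, key, [v.strip() for v in value.split(",") if v.strip()])
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        elif key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"line {line_no}: unknown key {key!r}")
    return cfg


def _write_matrix_tsv(path: Path, labels, matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(map(str, labels)) + "\n")
        for lab, row in zip(labels, np.asarray(matrix)):
            fh.write(str(lab) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(name: str, start: float, **shapes) -> None:
    info = " ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("%s: %s (%.2fs)", name, info, time.perf_counter() - start)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full analysis; returns a map of report name -> file path.

    Any stage failure aborts with the stage name in the exception; the
    output directory is only populated on success (reports are written
    at the end, after all computation).
    """
    cfg = config
    cfg.validate()
    scale = OrdinalScale()
    outdir = Path(cfg.outdir)

    t0 = time.perf_counter()
    roster, records = parse_y2h_table(cfg.y2h_path, scale)
    _stage("parse", t0, proteins=len(roster), records=len(records))

    t0 = time.perf_counter()
    roster, records = filter_regulators(roster, records, cfg.exclusions)
    _stage("filter", t0, proteins=len(roster), records=len(records))

    t0 = time.perf_counter()
    binary = build_binary_network(records, roster,
                                  xgal_threshold=scale.code(cfg.xgal_threshold),
                                  his3_threshold=cfg.his3_threshold)
    _stage("binarize", t0, edges=len(binary.edges()))

    weights = weight_presets()[cfg.weight_preset]
    t0 = time.perf_counter()
    valued = standardized_distance_matrix(records, roster, weights)
    _stage("standardize", t0, weights=weights)

    covset = None
    if "gaussian_regression" in cfg.families:
        if not cfg.covariate_paths:
            raise ValueError("gaussian_regression requested without covariates")
        mats = {name: read_phylip_square(p)
                for name, p in cfg.covariate_paths.items()}
        covset = align_covariates(mats, roster)

    scans: dict[str, pd.DataFrame] = {}
    best_fits = {}
    for family in cfg.families:
        t0 = time.perf_counter()
        if family == "bernoulli":
            X, Y = binary.Z.astype(float), None
        elif family in _VALUED_FAMILIES:
            X = np.nan_to_num(valued.X, nan=1.0)  # a missing pair is uninformative
            Y = covset if family == "gaussian_regression" else None
        else:
            raise ValueError(f"unknown family {family!r}")
        table, fits = model_scan(X, Y, family=family,
                                 Q_range=range(cfg.q_min, cfg.q_max + 1),
                                 n_restarts=cfg.n_restarts,
                                 random_state=cfg.seed)
        scans[family] = table
        bestQ = int(table.loc[table["best"], "Q"].iloc[0])
        best_fits[family] = (bestQ, fits[bestQ], X)
        _stage(f"scan[{family}]", t0, best_Q=bestQ)

    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def emit(name: str, filename: str) -> Path:
        p = outdir / filename
        paths[name] = str(p)
        return p

    _write_matrix_tsv(emit("binary_network", "binary_network.tsv"),
                      roster.proteins, binary.Z.astype(int))
    pd.DataFrame(binary.edges(), columns=["protein_a", "protein_b"]).to_csv(
        emit("binary_edges", "binary_edges.tsv"), sep="\t", index=False)
    _write_matrix_tsv(emit("valued_network", "valued_network.tsv"),
                      roster.proteins, valued.X)
    with open(emit("valued_weights", "valued_network_weights.json"), "w") as fh:
        json.dump({"w_xgal": weights[0], "w_his3": weights[1]}, fh, indent=2,
                  sort_keys=True)

    partitions = {}
    for family, table in scans.items():
        table.to_csv(emit(f"scan_{family}", f"scan_{family}.tsv"),
                     sep="\t", index=False)
        bestQ, fit, X = best_fits[family]
        D = profile_distance_matrix(X)
        diag = cluster_distance_matrix(D, fit.tau)
        members = membership_table(roster, fit.tau, D)
        members.to_csv(emit(f"clusters_{family}", f"clusters_{family}.tsv"),
                       sep="\t", index=False)
        _write_matrix_tsv(emit(f"cluster_distances_{family}",
                               f"cluster_distances_{family}.tsv"),
                          list(range(bestQ)), diag.cluster_cluster)
        payload = {
            "family": family,
            "Q": bestQ,
            "alpha": fit.params.alpha,
            "mu": fit.params.mu,
            "beta": fit.params.beta,
            "sigma2": fit.params.sigma2,
            "tau": fit.tau,
            "J": fit.J,
            "icl": fit.icl,
            "n_params": fit.n_params,
            "seed": cfg.seed,
        }
        with open(emit(f"best_fit_{family}", f"best_fit_{family}.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        partitions[family] = fit.labels

    fams = list(partitions)
    M = np.zeros((len(fams), len(fams)), dtype=int)
    for a, fa in enumerate(fams):
        for b, fb in enumerate(fams):
            M[a, b] = partition_match(partitions[fa], partitions[fb])[0]
    _write_matrix_tsv(emit("partition_match", "partition_match.tsv"), fams, M)

    manifest = {
        "auxnet_version": __version__,
        "python": sys.version.split()[0],
        "config": {k: v for k, v in asdict(cfg).items()},
        "n_proteins": len(roster),
        "reports": sorted(paths),
    }
    with open(emit("manifest", "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return paths
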