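"""End-to-end orchestration: read inputs, run every stage, write a report
bundle (landmark table, trend screen, correlations, clustering, PCA,
trait-trajectory plateaus, fold changes) plus a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .expression import delta_delta_ct
from .growth import fit_logistic, landmarks
from .screen import (
    assign_weight_groups,
    correlation_matrix,
    hierarchical_cluster,
    pca,
    screen_traits,
)
from .trajectory import fit_trait_curve, plateau_weight

logger = logging.getLogger("swinegrowth")

_FLOAT_FMT = "%.6g"  # 6 significant digits keeps report tables byte-stable

__all__ = ["RunConfig", "run_full_analysis", "read_weights", "read_trait_table",
           "read_ct_table", "write_landmark_table"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    weights_csv: str | None = None
    traits_csv: str | None = None
    qpcr_csv: str | None = None
    out_dir: str = "swinegrowth_out"
    breed_col: str = "breed"
    bw_col: str = "bw"
    # per-breed weight-bin start (kg); breeds absent here use the minimum
    # observed weight floored to the bin width
    bin_start: dict = field(default_factory=lambda: {"YP": 80.0, "QYP": 60.0})
    bin_width: float = 10.0
    n_groups: int = 8
    alpha: float = 0.05
    plateau_threshold: float = 0.1
    trajectory_traits: tuple = ("LMA", "IMF")
    reference_gene: str = "GAPDH"
    # calibrator group per breed prefix; None -> lexicographically first group
    calibrator_group: str | None = None
    seed: int = 17
    log_level: str = "INFO"


def _read_csv_checked(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    """Read a CSV and validate its schema; collect row-level problems."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(
            f"{path.name}: empty file, missing header {required}"
        ) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    problems: list[str] = []
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        for i in df.index[bad]:
            # +2: header line and 1-based numbering
            problems.append(f"line {i + 2}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = parsed
    if problems:
        raise SchemaError(
            f"{path.name}: {len(problems)} malformed value(s)", problems=problems
        )
    return df


def read_weights(path) -> pd.DataFrame:
    """Longitudinal weights CSV: animal_id, breed, age_days, weight_kg."""
    df = _read_csv_checked(
        path,
        required=["animal_id", "breed", "age_days", "weight_kg"],
        numeric=["age_days", "weight_kg"],
    )
    problems = []
    for i in df.index[(df["age_days"] <= 0) | (df["weight_kg"] <= 0)]:
        problems.append(
            f"line {i + 2}: non-positive age/weight "
            f"({df.loc[i, 'age_days']}, {df.loc[i, 'weight_kg']})"
        )
    if problems:
        raise SchemaError(f"weights: {len(problems)} invalid row(s)", problems)
    return df


def read_trait_table(path, breed_col: str = "breed", bw_col: str = "bw") -> pd.DataFrame:
    """Slaughter trait table CSV: animal_id, breed, bw, plus trait columns."""
    df = _read_csv_checked(path, required=[breed_col, bw_col], numeric=[bw_col])
    trait_cols = [
        c for c in df.columns if c not in ("animal_id", breed_col, bw_col)
    ]
    for col in trait_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_ct_table(path) -> pd.DataFrame:
    """Tidy qPCR table CSV: sample_id, group, gene, ct."""
    return _read_csv_checked(
        path, required=["sample_id", "group", "gene", "ct"], numeric=["ct"]
    )


def write_landmark_table(fits: dict, path) -> pd.DataFrame:
    """Write the per-breed landmark report (growth-model table layout).

    ``fits`` maps breed -> LogisticFit.  Columns: breed, n, pcc, A, B, K,
    P_BW, P_Age, MDG, max_decel_age, max_decel_weight.
    """
    rows = []
    for breed, fit in fits.items():
        lm = landmarks(fit.params)
        rows.append(
            {
                "breed": breed,
                "n": fit.n_animals,
                "pcc": fit.pcc,
                "A": fit.params.A,
                "B": fit.params.B,
                "K": fit.params.K,
                "P_BW": lm.inflection_weight,
                "P_Age": lm.inflection_age,
                "MDG": lm.max_daily_gain,
                "max_decel_age": lm.max_decel_age,
                "max_decel_weight": lm.max_decel_weight,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return df


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _bin_start_for(config: RunConfig, breed: str, bw: np.ndarray) -> float:
    if breed in config.bin_start:
        return float(config.bin_start[breed])
    return float(np.floor(bw.min() / config.bin_width) * config.bin_width)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``).  A stage
    failure is recorded in the manifest and downstream dependents are
    skipped; callers should treat any failed stage as a nonzero-exit
    condition.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    manifest: dict = {
        "package": "swinegrowth",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str, detail: str = "") -> None:
        manifest["stages"][stage] = {"status": status, "detail": detail}
        (logger.info if status == "ok" else logger.error)(
            "stage %s: %s %s", stage, status, detail
        )

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"].append(name)

    # ---- growth fitting + landmarks ----
    if config.weights_csv:
        try:
            weights = read_weights(config.weights_csv)
            fits = {
                breed: fit_logistic(sub)
                for breed, sub in weights.groupby(config.breed_col, sort=True)
            }
            lm_df = write_landmark_table(fits, out / "landmarks.csv")
            manifest["outputs"].append("landmarks.csv")
            record("growth", "ok", f"{len(lm_df)} breed(s)")
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            record("growth", "failed", str(exc))
    else:
        record("growth", "skipped", "no weights input")

    # ---- trait screening, correlations, clustering, PCA, trajectories ----
    if config.traits_csv:
        try:
            traits = read_trait_table(config.traits_csv, config.breed_col,
                                      config.bw_col)
            breeds = sorted(traits[config.breed_col].unique())
            if len(breeds) < 2:
                logger.warning(
                    "only one breed present; between-breed comparisons skipped"
                )
            trend_frames, plateau_rows = [], []
            for breed in breeds:
                sub = traits[traits[config.breed_col] == breed]
                bw = sub[config.bw_col].to_numpy(dtype=float)
                start = _bin_start_for(config, breed, bw)
                trend_frames.append(
                    screen_traits(
                        sub, breed, start, config.bin_width, config.n_groups,
                        alpha=config.alpha, bw_col=config.bw_col,
                    )
                )
                corr = correlation_matrix(
                    sub.drop(columns=["animal_id"], errors="ignore")
                )
                corr.to_csv(out / f"correlations_{breed}.csv",
                            float_format=_FLOAT_FMT)
                manifest["outputs"].append(f"correlations_{breed}.csv")
                groups = assign_weight_groups(
                    bw, start, config.bin_width, config.n_groups
                )
                means = (
                    sub.select_dtypes(include=[np.number])
                    .assign(weight_group=groups)
                    .query("weight_group > 0")
                    .groupby("weight_group")
                    .mean()
                    .drop(columns=[config.bw_col], errors="ignore")
                )
                if len(means) >= 2:
                    cl = hierarchical_cluster(
                        means, zscore=True,
                        n_clusters=min(3, len(means)),
                    )
                    emit(
                        pd.DataFrame(
                            {"weight_group": list(cl.items), "cluster": cl.labels}
                        ),
                        f"cluster_assignments_{breed}.csv",
                    )
                for trait_name in config.trajectory_traits:
                    if trait_name not in sub.columns:
                        continue
                    fit = fit_trait_curve(
                        bw, sub[trait_name].to_numpy(dtype=float),
                        model_form="auto", trait=trait_name, breed=breed,
                    )
                    pl = plateau_weight(fit, config.plateau_threshold)
                    plateau_rows.append(
                        {
                            "breed": breed,
                            "trait": trait_name,
                            "model_form": fit.model_form,
                            "plateau_weight": pl.plateau_weight,
                            "max_slope": pl.max_slope,
                            "threshold": config.plateau_threshold,
                        }
                    )
            emit(pd.concat(trend_frames, ignore_index=True), "trends.csv")
            pca_res = pca(
                traits.drop(columns=["animal_id"], errors="ignore")
            )
            scores = pca_res.scores.copy()
            scores.insert(0, "breed", traits[config.breed_col].to_numpy())
            scores.to_csv(out / "pca_scores.csv", index=False,
                          float_format=_FLOAT_FMT)
            manifest["outputs"].append("pca_scores.csv")
            if plateau_rows:
                emit(pd.DataFrame(plateau_rows), "plateaus.csv")
            record("screen", "ok", f"{len(breeds)} breed(s)")
        except Exception as exc:  # noqa: BLE001
            record("screen", "failed", str(exc))
    else:
        record("screen", "skipped", "no trait-table input")

    # ---- qPCR fold changes ----
    if config.qpcr_csv:
        try:
            ct = read_ct_table(config.qpcr_csv)
            frames = []
            groups = sorted(ct["group"].unique())
            prefixes = sorted({g.rsplit("_", 1)[0] if "_" in g else g
                               for g in groups})
            for prefix in prefixes:
                sub = ct[ct["group"].str.startswith(prefix)]
                if config.calibrator_group and config.calibrator_group in set(
                    sub["group"]
                ):
                    calib = config.calibrator_group
                else:
                    calib = sorted(sub["group"].unique())[0]
                res = delta_delta_ct(sub, config.reference_gene, calib)
                frames.append(res.summary)
            emit(pd.concat(frames, ignore_index=True), "fold_changes.csv")
            record("expression", "ok", f"{len(prefixes)} breed group(s)")
        except Exception as exc:  # noqa: BLE001
            record("expression", "failed", str(exc))
    else:
        record("expression", "skipped", "no qPCR input")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.removeHandler(handler)
    handler.close()
    return manifest
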