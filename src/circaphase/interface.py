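"""File I/O, run manifests and the ablation driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dcpr_core import DcprConfig, DcprResult, fit_dcpr
from .metrics import MetricsReport, PhaseVector, evaluate_phases
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_seed_list",
    "read_phases",
    "write_phases",
    "RunManifest",
    "run_ablation",
    "ABLATION_VARIANTS",
]

#: variant -> (augment_off, multistage_off)
ABLATION_VARIANTS = {
    "M0": (False, False),
    "M1": (True, False),
    "M2": (False, True),
    "M3": (True, True),
}


def read_expression(path, true_times_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV matrix (first column = gene ids).

    Non-numeric rows are dropped with a logged count; duplicate gene ids are
    suffixed deterministically (``id``, ``id.1``, ``id.2``, ...).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 sample columns")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: matrix has no gene rows")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "%s: dropped %d rows with non-numeric/missing cells",
            path.name,
            int(bad.sum()),
        )
        numeric = numeric.loc[~bad]
    if numeric.shape[0] == 0:
        raise ValueError(f"{path}: no numeric gene rows left")
    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene ids disambiguated", path.name, n_dup)
        counts: dict[str, int] = {}
        new_index = []
        for g in numeric.index:
            k = counts.get(g, 0)
            new_index.append(g if k == 0 else f"{g}.{k}")
            counts[g] = k + 1
        numeric.index = new_index
    true_times = None
    if true_times_path is not None:
        truth = pd.read_csv(true_times_path).set_index("sample_id")
        true_times = truth.loc[list(numeric.columns), "true_time_h"].to_numpy()
    return ExpressionMatrix(numeric, true_times)


def read_seed_list(path) -> list[str]:
    """Newline-delimited gene identifiers; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_phases(phases: PhaseVector, path) -> None:
    pd.DataFrame(
        {
            "sample_id": phases.sample_ids,
            "phase_rad": phases.phases_rad,
            "phase_h": phases.phases_h,
        }
    ).to_csv(path, index=False)


def read_phases(path) -> PhaseVector:
    df = pd.read_csv(path)
    return PhaseVector(df["phase_rad"].to_numpy(), list(df["sample_id"]))


@dataclass
class RunManifest:
    """Provenance record written next to every artifact-producing run."""

    command: str
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    ablation_variant: str = "M0"
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_ablation(
    matrix: ExpressionMatrix,
    config: DcprConfig,
    variant: str,
    seed_genes=None,
) -> tuple[DcprResult, MetricsReport]:
    """Run one ablation variant and evaluate it against true times.

    M0 = full pipeline, M1 = augmentation off, M2 = deep multi-stage
    representation off (plain two-unit autoencoder on Y or Z), M3 = both
    off.  Requires ``matrix.true_times``.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown ablation variant {variant!r}; expected one of "
            f"{sorted(ABLATION_VARIANTS)}"
        )
    if matrix.true_times is None:
        raise ValueError("ablation evaluation requires true collection times")
    augment_off, multistage_off = ABLATION_VARIANTS[variant]
    cfg = DcprConfig(
        **{
            **config.to_dict(),
            "augment_off": augment_off,
            "multistage_off": multistage_off,
        }
    )
    result = fit_dcpr(matrix, cfg, seed_genes=seed_genes)
    report = evaluate_phases(result.phases, np.mod(matrix.true_times, 24.0))
    return result, report
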