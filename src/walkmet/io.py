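"""Cohort table readers/writers, seed derivation and the pipeline driver.

Cohort files are plain two-column text: the 6MWT result (distance in meters
or average velocity in km/h) and the treadmill MET score, separated by any
whitespace or a comma.  The supplementary-table layout such files come in
is undocumented in practice, so the reader sniffs the delimiter, skips an
optional header line, and infers the first column's semantics from its
magnitude (median > 50 means meters) unless a dialect says otherwise.
Malformed lines are reported with their line numbers; nothing is silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .classification import (
    CONVENTIONAL_SCHEME,
    assign_cohort,
    scheme_from_model,
)
from .cohort import Cohort, WalkRecord
from .estimation import GAConfig, fit_piecewise, fit_polynomial
from .synthetic import SyntheticConfig, generate_by_sex
from .validation import PiecewiseSpec, PolynomialSpec, loo_cv

__all__ = [
    "CohortDialect",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "derive_seed",
    "run_pipeline",
]


class CohortParseError(ValueError):
    """A cohort file failed to parse; the message names the offending line."""


@dataclass(frozen=True)
class CohortDialect:
    """How to interpret a two-column cohort table.

    ``first_column`` is one of ``"distance_m"``, ``"velocity_kmh"`` or
    ``"auto"`` (magnitude heuristic: median first-column value above 50
    implies meters).  Delimiter is any run of whitespace and/or commas; the
    decimal separator is the point.
    """

    first_column: str = "auto"

    def __post_init__(self) -> None:
        if self.first_column not in ("auto", "distance_m", "velocity_kmh"):
            raise ValueError(f"unknown column semantics {self.first_column!r}")


def _split_line(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_cohort(
    path: str | Path, dialect: CohortDialect = CohortDialect(), label: str = ""
) -> Cohort:
    """Read a two-column cohort table into a Cohort (velocities in km/h)."""
    path = Path(path)
    rows: list[tuple[float, float]] = []
    lines = path.read_text().splitlines()
    start = 0
    # header auto-detection: a first non-empty line with non-numeric cells
    for i, line in enumerate(lines):
        if line.strip():
            cells = _split_line(line)
            try:
                [float(c) for c in cells]
            except ValueError:
                start = i + 1
            break
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cells = _split_line(line)
        if len(cells) != 2:
            raise CohortParseError(
                f"{path.name}:{lineno}: expected 2 columns, got {len(cells)}"
            )
        try:
            x, met = float(cells[0]), float(cells[1])
        except ValueError:
            raise CohortParseError(
                f"{path.name}:{lineno}: non-numeric cell in {line.strip()!r}"
            ) from None
        if x < 0:
            raise CohortParseError(f"{path.name}:{lineno}: negative 6MWT result {x}")
        if met <= 0:
            raise CohortParseError(f"{path.name}:{lineno}: non-positive MET {met}")
        rows.append((x, met))
    if not rows:
        raise CohortParseError(f"{path.name}: no data rows")

    first = np.array([r[0] for r in rows])
    semantics = dialect.first_column
    if semantics == "auto":
        semantics = "distance_m" if np.median(first) > 50 else "velocity_kmh"
    velocities = first / 100.0 if semantics == "distance_m" else first
    return Cohort(
        velocities=velocities,
        mets=np.array([r[1] for r in rows]),
        label=label or path.stem,
    )


def write_cohort(
    cohort: Cohort, path: str | Path, first_column: str = "velocity_kmh"
) -> None:
    """Write a cohort as a two-column whitespace table with a header line."""
    path = Path(path)
    if first_column not in ("distance_m", "velocity_kmh"):
        raise ValueError(f"unknown column semantics {first_column!r}")
    col = cohort.distances if first_column == "distance_m" else cohort.velocities
    header = f"{first_column} met"
    body = "\n".join(f"{x:.10g} {m:.10g}" for x, m in zip(col, cohort.mets))
    path.write_text(header + "\n" + body + "\n")


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, from one top-level seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Fit, cross-validate and classify each population; write JSON reports.

    Config sections: ``input`` (either ``{"men": path, "women": path}`` or
    ``{"synthetic": {...SyntheticConfig fields...}}``), optional ``models``
    (``polynomial_order``, ``n_segments``), ``ga`` (GAConfig fields),
    ``validation`` (``enabled``, ``piecewise_mode``), ``seed``.  The 'all'
    population is always the concatenation men + women.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs = config.get("input")
    if not inputs:
        raise ValueError("pipeline config needs an 'input' section")

    if "synthetic" in inputs:
        synth = SyntheticConfig(
            **{**inputs["synthetic"], "seed": derive_seed(seed, "synthetic")}
        )
        men, women = generate_by_sex(synth)
    elif "men" in inputs and "women" in inputs:
        men = read_cohort(inputs["men"], label="men")
        women = read_cohort(inputs["women"], label="women")
    else:
        raise ValueError("'input' must give either 'synthetic' or 'men'+'women' paths")
    populations = {
        "men": men,
        "women": women,
        "all": Cohort.concat([men, women], label="all"),
    }

    model_cfg = config.get("models", {})
    order = int(model_cfg.get("polynomial_order", 3))
    n_segments = int(model_cfg.get("n_segments", 4))
    ga = GAConfig(**config.get("ga", {}))
    val_cfg = config.get("validation", {})

    summary: dict = {"seed": seed, "config_hash": _config_hash(dict(config)), "populations": {}}
    for name, cohort in populations.items():
        entry: dict = {"n": len(cohort)}
        poly = fit_polynomial(cohort, order)
        pw = fit_piecewise(
            cohort, n_segments, GAConfig(**{**ga.__dict__, "seed": derive_seed(seed, f"fit:{name}")})
        )
        entry["polynomial"] = poly.to_dict()
        entry["piecewise"] = pw.to_dict()
        if val_cfg.get("enabled", False):
            cv_seed = derive_seed(seed, f"cv:{name}")
            entry["cv_polynomial"] = loo_cv(cohort, PolynomialSpec(order), cv_seed).to_dict()
            entry["cv_piecewise"] = loo_cv(
                cohort,
                PiecewiseSpec(
                    n_segments,
                    GAConfig(**{**ga.__dict__, "seed": cv_seed}),
                    refit_change_points=val_cfg.get("piecewise_mode", "refit") == "refit",
                ),
                cv_seed,
            ).to_dict()
        if pw.model.n_segments == 4:
            scheme = scheme_from_model(pw.model)
            _, counts = assign_cohort(cohort, scheme)
            _, conv_counts = assign_cohort(cohort, CONVENTIONAL_SCHEME)
            entry["classification"] = {
                "model_derived_boundaries": list(scheme.boundaries),
                "model_derived_counts": counts,
                "conventional_counts": conv_counts,
            }
        (out_dir / f"{name}.json").write_text(json.dumps(entry, indent=2, sort_keys=True))
        summary["populations"][name] = entry
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
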