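"""Ensemble reports and region-map figures.

Reports are plain JSON: per-member areas/GAPI/goodness of fit, the
simple-average summary, and the full run configuration (seed, layer width,
buffer radius, grid resolution, noise level, replicate count) so a rerun is
reproducible from the report alone. A JSON schema document ships with the
package (``ensemble_report.schema.json``) and :func:`validate_report` checks
a report against it structurally.

Figures follow the field's convention: adaptation region in yellow,
maladaptation in blue, white separating boundary, numbered week dots
coloured by their observed label (green above 100% of personal best, red
below), misclassified weeks ringed in black.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .ensemble import EnsembleResult, GapiResult
from .geometry import DomainMap, LabelledPoint

_REGION_CMAP = ListedColormap(["#4c72b0", "#f2f2f2", "#f7d842"])  # -1, neutral, +1


def _member_dict(m: GapiResult) -> dict[str, Any]:
    return {
        "area_adapt": m.area_adapt,
        "area_malad": m.area_malad,
        "area_neutral": m.area_neutral,
        "gapi": None if math.isinf(m.gapi) else m.gapi,
        "gapi_infinite": math.isinf(m.gapi),
        "goodness_of_fit": m.goodness_of_fit,
        "mce": m.mce,
        "per_point": {
            str(week): {"label": lab, "predicted": pred, "correct": bool(ok)}
            for week, (lab, pred, ok) in sorted(m.per_point.items())
        },
    }


def ensemble_report(
    athlete_id: str,
    combo: int,
    result: EnsembleResult,
    *,
    layer_width: float,
    buffer_radius: float,
    grid_resolution: int,
) -> dict[str, Any]:
    """JSON-serialisable report for one athlete x combination ensemble."""
    return {
        "athlete_id": athlete_id,
        "combination": combo,
        "mean_gapi": None if math.isinf(result.mean_gapi) else result.mean_gapi,
        "mean_gof": result.mean_gof,
        "gapi_sd": result.gapi_sd,
        "degenerate_members": result.degenerate_members,
        "misclassified_weeks": sorted(
            {
                week
                for m in result.members
                for week, (_, _, ok) in m.per_point.items()
                if not ok
            }
        ),
        "config": {
            "seed": result.config.seed,
            "noise_level": result.config.noise_level,
            "replicates": result.config.replicates,
            "multiplicative": result.config.multiplicative,
            "layer_width": layer_width,
            "buffer_radius": buffer_radius,
            "grid_resolution": grid_resolution,
        },
        "members": [_member_dict(m) for m in result.members],
    }


def load_schema() -> dict[str, Any]:
    text = (
        resources.files("adaptgeom").joinpath("ensemble_report.schema.json").read_text()
    )
    return json.loads(text)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(node: Any, schema: dict[str, Any], path: str, errors: list[str]) -> None:
    stype = schema.get("type")
    if stype is None:
        return
    types = stype if isinstance(stype, list) else [stype]
    if "null" in types and node is None:
        return
    expected = tuple(
        t for s in types if s != "null" for t in (lambda m: m if isinstance(m, tuple) else (m,))(_TYPE_MAP[s])
    )
    if not isinstance(node, expected) or (
        isinstance(node, bool) and bool not in expected
    ):
        errors.append(f"{path}: expected {types}, got {type(node).__name__}")
        return
    if isinstance(node, dict):
        for key in schema.get("required", []):
            if key not in node:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check(node[key], sub, f"{path}.{key}", errors)
    elif isinstance(node, list) and "items" in schema:
        for i, item in enumerate(node):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict[str, Any]) -> list[str]:
    """Structural check of a report against the shipped schema.

    Returns the list of violations (empty when the report conforms).
    """
    errors: list[str] = []
    _check(report, load_schema(), "$", errors)
    return errors


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def plot_domain_map(
    domain_map: DomainMap,
    points: Sequence[LabelledPoint] = (),
    per_point: dict[int, tuple[int, int, bool]] | None = None,
    path: str | Path | None = None,
    title: str | None = None,
) -> plt.Figure:
    """Region map in the standard style; writes SVG/PNG when ``path`` set."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(
        domain_map.labels,
        origin="lower",
        extent=(0, 1, 0, 1),
        cmap=_REGION_CMAP,
        vmin=-1,
        vmax=1,
        interpolation="nearest",
    )
    for line in domain_map.boundary:
        ax.plot(line[:, 0], line[:, 1], color="white", lw=2)
    for p in points:
        colour = "#2ca02c" if p.label == 1 else "#d62728"
        wrong = per_point is not None and not per_point.get(p.week, (0, 0, True))[2]
        ax.scatter(
            *p.p,
            s=260,
            color=colour,
            edgecolors="black" if wrong else "none",
            linewidths=2.5,
            zorder=3,
        )
        ax.annotate(
            str(p.week),
            p.p,
            ha="center",
            va="center",
            fontsize=8,
            color="white",
            zorder=4,
        )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("x (normalised)")
    ax.set_ylabel("y (normalised)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
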