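"""Orchestration: rerun the published analysis and render reports.

:func:`reproduce_paper` reruns Bayesian model selection on every response
variable of the packaged per-pen organ/lipid table and sets the results
side-by-side with the published statistics (best model, maximum posterior
probability, BF12, evidence label), reporting absolute differences but never
asserting agreement — assertions belong to the test suite.  It also
evaluates the published steatosis score lines at 0 and 24 % rapeseed oil.

Reports serialise deterministically to JSON or markdown.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .bayes import PriorSpec, select_model
from .steatosis import (
    LARGE_FISH_LINE,
    SMALL_FISH_LINE,
    round1,
    score_at,
    score_shift,
)
from .trial_data import TABLE5_VARIABLES, fixture, organ_lipid_table

__all__ = [
    "RunConfig",
    "REPORT_SCHEMA_VERSION",
    "reproduce_paper",
    "render_report",
    "validate_report",
]

logger = logging.getLogger("salmotrial")

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Settings for a reproduction run."""

    variables: tuple[str, ...] = TABLE5_VARIABLES
    prior: PriorSpec = field(default_factory=PriorSpec)
    report_format: str = "json"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.report_format not in ("json", "markdown"):
            raise ValueError("report_format must be 'json' or 'markdown'")
        unknown = set(self.variables) - set(TABLE5_VARIABLES)
        if unknown:
            raise ValueError(f"unknown variables: {sorted(unknown)}")


def _config_hash(config: RunConfig) -> str:
    text = json.dumps(
        {
            "variables": list(config.variables),
            "prior": dataclasses.asdict(config.prior),
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def reproduce_paper(config: RunConfig | None = None) -> dict:
    """Rerun model selection on the packaged pen table; compare with print.

    Any per-variable failure is captured as an ``error`` entry so the rest
    of the report still renders.
    """
    config = config or RunConfig()
    logger.info(
        "reproduce-paper version=%s config=%s seed=%d prior=%s",
        __version__, _config_hash(config), config.seed, config.prior,
    )
    table = organ_lipid_table()
    printed = fixture("organ_lipid_stats").set_index("variable")

    variables: dict[str, dict] = {}
    for name in config.variables:
        row = printed.loc[name]
        entry: dict = {
            "printed": {
                "best_model": str(row["best_model"]),
                "probability": float(row["probability"]),
                "bf12": float(row["bf12"]),
                "evidence": str(row["evidence"]),
            }
        }
        try:
            res = select_model(table, name, config.prior)
            entry["computed"] = {
                "best_model": res.best_model,
                "probability": res.probabilities[res.best_model],
                "bf12": res.bf12,
                "evidence": res.evidence,
                "log_marginals": res.log_marginals,
                "probabilities": res.probabilities,
                "ks_p": res.diagnostics.ks_p,
                "ks_pass": res.diagnostics.passed,
            }
            entry["abs_diff"] = {
                "probability": abs(
                    entry["computed"]["probability"] - entry["printed"]["probability"]
                ),
                "best_model_match": res.best_model == entry["printed"]["best_model"],
            }
        except Exception as exc:  # partial report on per-variable failure
            entry["error"] = f"{type(exc).__name__}: {exc}"
        variables[name] = entry

    lines = {}
    for label, line in (("small", SMALL_FISH_LINE), ("large", LARGE_FISH_LINE)):
        lines[label] = {
            "slope": line.slope,
            "intercept": line.intercept,
            "score_at_0": round1(score_at(line, 0.0)),
            "score_at_24": round1(score_at(line, 24.0)),
            "shift_0_to_24": round1(score_shift(line, 0.0, 24.0)),
        }
    lines["size_difference_at_0"] = round1(
        score_at(SMALL_FISH_LINE, 0.0) - score_at(LARGE_FISH_LINE, 0.0)
    )

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "prior": dataclasses.asdict(config.prior),
        "variables": variables,
        "score_lines": lines,
        "note": (
            "Printed values are shown for side-by-side comparison only; "
            "differences are reported, not asserted."
        ),
    }


def validate_report(report: dict) -> None:
    """Structural check of a reproduction report (the shipped JSON schema).

    Raises ``ValueError`` on the first violation.
    """
    for key in ("schema_version", "package_version", "variables", "score_lines"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {report['schema_version']!r}")
    if not report["variables"]:
        raise ValueError("report has no variables")
    for name, entry in report["variables"].items():
        if "printed" not in entry:
            raise ValueError(f"variable {name!r} missing printed block")
        if "computed" not in entry and "error" not in entry:
            raise ValueError(f"variable {name!r} has neither computed nor error")
        if "computed" in entry:
            probs = entry["computed"]["probabilities"]
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"probabilities of {name!r} do not sum to 1")


def render_report(results: dict, fmt: str, path: str | Path) -> Path:
    """Serialise a report deterministically to ``path``.

    JSON output is byte-stable for equal inputs; markdown mirrors the
    published statistics layout (one row per variable).
    """
    if not results or not results.get("variables"):
        raise ValueError("cannot render an empty report")
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps(results, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
    elif fmt == "markdown":
        rows = [
            "| variable | best (computed) | best (printed) | prob (computed) "
            "| prob (printed) | BF12 (computed) | evidence |",
            "|---|---|---|---|---|---|---|",
        ]
        for name in sorted(results["variables"]):
            entry = results["variables"][name]
            if "error" in entry:
                rows.append(f"| {name} | error: {entry['error']} | | | | | |")
                continue
            c, p = entry["computed"], entry["printed"]
            rows.append(
                f"| {name} | {c['best_model']} | {p['best_model']} "
                f"| {c['probability']:.3f} | {p['probability']:.3f} "
                f"| {c['bf12']:.1f} | {c['evidence']} |"
            )
        lines = results.get("score_lines", {})
        tail = [
            "",
            "Score lines (published first-degree fits, 1-dp presentation):",
            "",
        ]
        for label in ("small", "large"):
            if label in lines:
                li = lines[label]
                tail.append(
                    f"- {label}: score(0%) = {li['score_at_0']}, "
                    f"score(24%) = {li['score_at_24']}, "
                    f"shift = {li['shift_0_to_24']}"
                )
        if "size_difference_at_0" in lines:
            tail.append(
                f"- size difference at 0%: {lines['size_difference_at_0']}"
            )
        tail.append("")
        tail.append("All requirement-related quantities are indications, "
                    "not requirement estimates.")
        path.write_text("\n".join(rows + tail) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
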