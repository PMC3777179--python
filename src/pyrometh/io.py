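"""Structured-text configuration and tabular report I/O.

Assay definitions travel as YAML; peak tables, methylation reports and
comparison tables as tab-separated text; run summaries as JSON carrying
the seed and every threshold, so any run can be reproduced from its
outputs alone.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import __version__
from .assay import AssayDefinition, Primer
from .dispense import DispensationOrder, generate_dispensation
from .pyro import MethylationCall
from .seqcore import DegenerateSequence
from .study import ComparisonResult, ReplicateSet


class ConfigError(ValueError):
    """Malformed configuration file."""


def _load_yaml(path: Union[str, Path]) -> dict:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data


def _build_assay(entry: dict, path) -> AssayDefinition:
    try:
        primers = {
            role: Primer(role=role, **entry["primers"][role])
            for role in ("forward", "reverse", "sequencing")
        }
        sta = DegenerateSequence(
            bases=entry["sequence_to_analyze"],
            source_id=f"{entry['name']}_sequence_to_analyze",
        )
        order = entry.get("dispensation_order", "auto")
        if order == "auto":
            order = generate_dispensation(sta).bases
        return AssayDefinition(
            name=entry["name"],
            reference_id=entry.get("reference", ""),
            forward=primers["forward"],
            reverse=primers["reverse"],
            sequencing=primers["sequencing"],
            sequence_to_analyze=sta,
            dispensation_order=order,
            declared_amplicon_bp=entry.get("amplicon_bp"),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: assay entry missing field {exc}") from exc


def load_assays(path: Union[str, Path]) -> dict[str, AssayDefinition]:
    """Load assay definitions from a YAML config (see data/assays.yaml)."""
    data = _load_yaml(path)
    entries = data.get("assays")
    if not isinstance(entries, list) or not entries:
        raise ConfigError(f"{path}: expected a non-empty 'assays' list")
    out = {}
    for entry in entries:
        a = _build_assay(entry, path)
        out[a.name] = a
    return out


def packaged_assays() -> dict[str, AssayDefinition]:
    """The two self-designed LINE1 assays shipped with the package."""
    with resources.as_file(
        resources.files("pyrometh").joinpath("data/assays.yaml")
    ) as path:
        return load_assays(path)


def packaged_kit() -> tuple[DegenerateSequence, DispensationOrder]:
    """The commercial LINE1 kit's sequence-to-analyze / dispensation pair.

    The kit's printed order interleaves controls in an unpublished pattern,
    so it is honored verbatim (no control marks) and only validated.
    """
    with resources.as_file(
        resources.files("pyrometh").joinpath("data/line1_kit.yaml")
    ) as path:
        data = _load_yaml(path)
    seq = DegenerateSequence(bases=data["sequence_to_analyze"], source_id="line1_kit")
    return seq, DispensationOrder.from_string(data["dispensation_order"])


# --- reports ---------------------------------------------------------------

def write_methylation_report(
    call: MethylationCall, path: Union[str, Path], precise: bool = False
) -> None:
    """Per-site methylation report as TSV.

    User reports round percentages to the nearest integer (the convention
    of instrument displays); ``precise`` keeps full precision.
    """
    rows = [
        {
            "site": i + 1,
            "percent": p if precise else int(round(p)),
            "quality": q,
        }
        for i, (p, q) in enumerate(zip(call.per_site_percent, call.per_site_quality))
    ]
    df = pd.DataFrame(rows, columns=["site", "percent", "quality"])
    with open(path, "w") as fh:
        fh.write(f"# conversion_check\t{call.conversion_check}\n")
        total = call.total_percent
        fh.write(f"# total_percent\t{total if precise else int(round(total))}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_methylation_report(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def comparison_table(
    a: ReplicateSet,
    b: ReplicateSet,
    results: Union[ComparisonResult, tuple[ComparisonResult, ...]],
) -> pd.DataFrame:
    """Tidy comparison table: one row per (condition, tested quantity)."""
    if isinstance(results, ComparisonResult):
        results = (results,)
    rows = []
    for r in results:
        for cond, mean_, n_, vals in (
            (a.condition, r.group_means[0], r.n[0], a),
            (b.condition, r.group_means[1], r.n[1], b),
        ):
            if r.label == "total":
                sd = float(vals.totals.std(ddof=1))
            else:
                site = int(r.label.split("_")[1]) - 1
                sd = float(vals.site_matrix[:, site].std(ddof=1))
            rows.append(
                {
                    "quantity": r.label,
                    "condition": cond,
                    "n": n_,
                    "mean": mean_,
                    "sd": sd,
                    "t": r.t_statistic,
                    "p": r.p_value,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)


def write_comparison_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_comparison_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_summary(path: Union[str, Path], **fields) -> None:
    """Machine-readable run summary (full precision, seed, version, thresholds)."""
    payload = {"tool": "pyrometh", "version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
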