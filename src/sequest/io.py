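"""TSV/JSON serialization with reproducible 17-significant-digit decimals.

Distributions go to two-column TSV (``T<TAB>P``) with ``#``-prefixed header
lines carrying the full parameter set; joint tables and sweeps go to
long-format TSV; summaries to flat JSON.  Every writer lands atomically
(temp file + rename) so a failure never leaves a partial file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import DiscreteDistribution, JointDistribution

__all__ = [
    "format_float",
    "write_distribution_tsv",
    "read_distribution_tsv",
    "write_joint_tsv",
    "write_table_tsv",
    "read_table_tsv",
    "write_summary_json",
]


def format_float(x: float) -> str:
    return format(float(x), ".17g")


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header(params: Mapping[str, object]) -> str:
    lines = [f"# {k} = {params[k]}" for k in params]
    return "\n".join(lines) + "\n" if lines else ""


def write_distribution_tsv(
    path: str, dist: DiscreteDistribution, params: Mapping[str, object]
) -> None:
    rows = [f"{t}\t{format_float(p)}" for t, p in zip(dist.support, dist.probs)]
    text = _header(params) + "T\tP\n" + "\n".join(rows) + "\n"
    _atomic_write(path, text)


def read_distribution_tsv(path: str) -> tuple[DiscreteDistribution, dict[str, str]]:
    params: dict[str, str] = {}
    support: list[int] = []
    probs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                params[key.strip()] = value.strip()
                continue
            if line.startswith("T\t"):
                continue
            t, p = line.split("\t")
            support.append(int(t))
            probs.append(float(p))
    if support != list(range(support[0], support[0] + len(support))):
        raise ValueError("distribution support is not consecutive")
    return DiscreteDistribution(support[0], np.array(probs)), params


def write_joint_tsv(
    path: str,
    joint: JointDistribution,
    params: Mapping[str, object],
    colnames: tuple[str, ...] = ("T1", "T2"),
) -> None:
    """Long-format table: one row per grid cell, zero cells included."""
    if len(colnames) != joint.ndim:
        raise ValueError("one column name per axis is required")
    grids = np.meshgrid(*[joint.axis_support(a) for a in range(joint.ndim)], indexing="ij")
    rows = []
    flat = [g.ravel() for g in grids]
    for values, p in zip(zip(*flat), joint.table.ravel()):
        rows.append("\t".join(str(int(v)) for v in values) + "\t" + format_float(p))
    text = _header(params) + "\t".join(colnames) + "\tP\n" + "\n".join(rows) + "\n"
    _atomic_write(path, text)


def write_table_tsv(path: str, table: pd.DataFrame, params: Mapping[str, object]) -> None:
    body = table.to_csv(sep="\t", index=False, float_format="%.17g")
    _atomic_write(path, _header(params) + body)


def read_table_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_summary_json(path: str, summary: Mapping[str, object]) -> None:
    _atomic_write(path, json.dumps(summary, indent=2, sort_keys=True) + "\n")
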