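"""File formats and normalisation utilities.

Two plain TSV dialects are used throughout:

* expression data (wide): header ``series<TAB>time<TAB><gene...>``, one row
  per sample, several series stacked and distinguished by the ``series``
  column, times in native units;
* network edge lists: one row per nonzero kinetic order with columns
  ``regulator  target  phase  kinetic_order  delay_ts  delay_native``.
  Gold-standard and inferred networks share this dialect, so evaluation
  needs a single parser.

All writers are deterministic: stable row ordering and a fixed 6-significant-
digit float format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .dynamics import SeriesBlock, TimeSeriesSet
from .evaluation import GoldNetwork, _kinetic_tensors

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "normalize_max",
    "write_network_tsv",
    "read_network_tsv",
    "load_config",
]

_FMT = "{:.6g}".format


def read_expression_tsv(path, ts_unit: float | None = None) -> TimeSeriesSet:
    """Parse a wide expression TSV.  ``ts_unit`` defaults to the median
    sampling interval (so delays are expressed in sample spacings)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "series" or df.columns[1] != "time":
        raise ValueError(f"{path}: header must start with 'series<TAB>time'")
    gene_names = list(df.columns[2:])
    if not gene_names:
        raise ValueError(f"{path}: no gene columns found")
    for col in df.columns[1:]:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {bad + 2}")
    blocks = []
    for sid, grp in df.groupby("series", sort=True):
        times = grp["time"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: non-monotone time in series {sid!r}")
        values = grp[gene_names].to_numpy(dtype=float)
        if np.any(values <= 0):
            raise ValueError(f"{path}: non-positive expression in series {sid!r}")
        blocks.append(SeriesBlock(times, values))
    if ts_unit is None:
        ts_unit = float(np.median(np.concatenate([np.diff(b.times) for b in blocks])))
    return TimeSeriesSet(blocks, gene_names, ts_unit)


def write_expression_tsv(data: TimeSeriesSet, path) -> None:
    rows = []
    for m, blk in enumerate(data.series):
        for t, vals in zip(blk.times, blk.values):
            rows.append([m, _FMT(t)] + [_FMT(v) for v in vals])
    df = pd.DataFrame(rows, columns=["series", "time"] + list(data.gene_names))
    df.to_csv(path, sep="\t", index=False)


def normalize_max(data: TimeSeriesSet) -> TimeSeriesSet:
    """Divide each gene's profile by its maximum across all series jointly
    (after this every gene peaks at 1; idempotent)."""
    maxima = np.max([blk.values.max(axis=0) for blk in data.series], axis=0)
    if np.any(maxima <= 0):
        raise ValueError("every gene needs a positive maximum")
    out = [SeriesBlock(blk.times.copy(), blk.values / maxima) for blk in data.series]
    return TimeSeriesSet(out, list(data.gene_names), data.ts_unit)


def write_network_tsv(net, ts_unit: float, path, gene_names=None) -> None:
    """Write the nonzero regulations of an inferred (or gold) network as an
    edge list, ordered by (target, phase, regulator)."""
    K, tau = _kinetic_tensors(net)
    n = K.shape[1]
    if gene_names is None:
        gene_names = [f"G{j + 1}" for j in range(n)]
    rows = []
    for i in range(n):  # target-major ordering
        for phase, phase_name in enumerate(("production", "degradation")):
            for j in range(n):
                if K[phase, i, j] == 0:
                    continue
                d_ts = float(tau[phase, i, j])
                rows.append(
                    [
                        gene_names[j],
                        gene_names[i],
                        phase_name,
                        _FMT(K[phase, i, j]),
                        _FMT(d_ts),
                        _FMT(d_ts * ts_unit),
                    ]
                )
    df = pd.DataFrame(
        rows,
        columns=["regulator", "target", "phase", "kinetic_order", "delay_ts", "delay_native"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_network_tsv(path, gene_names=None) -> GoldNetwork:
    """Read an edge-list TSV back into a gold-network tensor triple.  The
    gene universe is ``gene_names`` when given, else the names seen in the
    file (sorted)."""
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "phase", "kinetic_order", "delay_ts"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if gene_names is None:
        gene_names = sorted(set(df["regulator"]) | set(df["target"]))
    index = {g: k for k, g in enumerate(gene_names)}
    n = len(gene_names)
    K = np.zeros((2, n, n))
    tau = np.zeros((2, n, n))
    for row in df.itertuples(index=False):
        phase = {"production": 0, "degradation": 1}.get(row.phase)
        if phase is None:
            raise ValueError(f"{path}: unknown phase {row.phase!r}")
        try:
            i, j = index[row.target], index[row.regulator]
        except KeyError as e:
            raise ValueError(f"{path}: gene {e} not in the gene universe") from None
        K[phase, i, j] = row.kinetic_order
        tau[phase, i, j] = row.delay_ts
    present = K != 0
    return GoldNetwork(present, np.sign(K).astype(int), np.where(present, tau, 0.0))


def load_config(path, **overrides):
    """Read a TDE configuration from YAML (``key: value``) or flat
    ``key=value`` lines; keyword overrides win."""
    from .optimizer import TDEConfig

    text = open(path).read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = yaml.safe_load(value.strip())
    valid = set(TDEConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    data.update(overrides)
    return TDEConfig(**data)
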