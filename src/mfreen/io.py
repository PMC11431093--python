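"""Delimited-text I/O, result serialization, and the seeded fixture builder.

Series travel as plain delimited text: rows are time samples, columns are
bands/variates, with an optional header row of band labels. Numeric output is
written at 17 significant digits so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EmbeddingConfig,
    EntropyResult,
    MultibandSeries,
    compute_entropy,
)
from .experiments import SweepResult, child_seed
from .simulate import MixParams, NoiseSpec, mix_signal, one_over_f_noise, white_gaussian_noise

__all__ = [
    "read_series",
    "write_series",
    "write_result",
    "result_record",
    "make_fixtures",
]

RESULT_COLUMNS = [
    "algorithm", "m", "tau", "r", "value", "normalized", "n_samples", "n_bands",
]


def read_series(path, has_header: bool | None = None, delimiter: str = ",") -> MultibandSeries:
    """Read an N x g delimited numeric matrix into a MultibandSeries.

    ``has_header=None`` auto-detects: a first row with any non-numeric cell
    is taken as band labels. Ragged rows, non-numeric body cells and empty
    files each raise a distinct diagnostic naming the offending row/column.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter) if row]
    if not rows:
        raise ValueError(f"{path}: file is empty")

    def _numeric_row(row):
        try:
            vals = [float(c) for c in row]
        except ValueError:
            return None
        return vals

    labels: tuple[str, ...] = ()
    first = _numeric_row(rows[0])
    if has_header is True or (has_header is None and first is None):
        labels = tuple(c.strip() for c in rows[0])
        body = rows[1:]
        if not body:
            raise ValueError(f"{path}: header but no data rows")
    else:
        body = rows

    width = len(body[0])
    values = np.empty((len(body), width))
    for i, row in enumerate(body):
        rownum = i + 1 + bool(labels)
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {rownum} ({len(row)} cells, expected {width})"
            )
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {rownum}, column {j + 1}"
                ) from None
            if not math.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value at row {rownum}, column {j + 1}"
                )
            values[i, j] = v
    return MultibandSeries(values=values, band_labels=labels)


def write_series(series: MultibandSeries, path, delimiter: str = ",") -> None:
    """Write a MultibandSeries as delimited text with a header row."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(series.band_labels)
        for row in series.values:
            writer.writerow([repr(float(v)) for v in row])


def result_record(result: EntropyResult) -> dict:
    """Flat dict form of an EntropyResult (the 8 declared output columns)."""
    cfg = result.config
    return {
        "algorithm": result.algorithm,
        "m": cfg.m,
        "tau": cfg.tau,
        "r": cfg.r if cfg.r is not None else cfg.r_factor,
        "value": result.value,
        "normalized": result.normalized,
        "n_samples": result.n_samples,
        "n_bands": result.n_bands,
    }


def write_result(result, path) -> None:
    """Serialize an EntropyResult (single CSV/JSON file) or a SweepResult
    (directory with raw.csv, summary.csv, params.json)."""
    path = Path(path)
    if isinstance(result, EntropyResult):
        record = result_record(result)
        if path.suffix.lower() == ".json":
            with open(path, "w") as fh:
                json.dump(record, fh, indent=2)
                fh.write("\n")
        else:
            pd.DataFrame([record]).to_csv(path, index=False)
    elif isinstance(result, SweepResult):
        path.mkdir(parents=True, exist_ok=True)
        result.raw.to_csv(path / "raw.csv", index=False)
        result.summary.to_csv(path / "summary.csv", index=False)
        with open(path / "params.json", "w") as fh:
            json.dump(result.params, fh, indent=2, default=str)
            fh.write("\n")
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")


def _tiny_series(rng, n, g) -> MultibandSeries:
    return MultibandSeries(rng.integers(0, 10, size=(n, g)).astype(float))


def make_fixtures(master_seed: int, out_dir) -> dict:
    """Emit the small seeded test inputs and a manifest of expected values.

    Writes tiny integer-valued series (<= 12 samples) exercising all three
    estimators, plus a 1500-sample MIX/WGN/1-over-f trio, and a manifest
    JSON holding the entropy values the estimators produce on them (the test
    suite re-derives these with independent brute-force implementations).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": int(master_seed), "entropies": {}}

    def _val(series, algo, cfg):
        res = compute_entropy(series, algo, cfg)
        return res.value if res.defined else None  # None: undefined (no matches)

    rng = np.random.default_rng(child_seed(master_seed, 0))
    tiny = {
        "tiny_univariate.csv": _tiny_series(rng, 12, 1),
        "tiny_bivariate.csv": _tiny_series(rng, 10, 2),
        "tiny_threeband.csv": _tiny_series(rng, 6, 3),
    }
    for name, series in tiny.items():
        write_series(series, out_dir / name)
    cfg2 = EmbeddingConfig(m=2, tau=1, r=1.5)
    manifest["entropies"]["tiny_univariate.csv"] = {
        "mvPerEn(m=3)": _val(tiny["tiny_univariate.csv"], "mvPerEn", EmbeddingConfig(m=3)),
        "mvSampEn(m=2,r=1.5)": _val(tiny["tiny_univariate.csv"], "mvSampEn", cfg2),
    }
    manifest["entropies"]["tiny_bivariate.csv"] = {
        "mvPerEn(m=2)": _val(tiny["tiny_bivariate.csv"], "mvPerEn", cfg2),
        "mvSampEn(m=2,r=1.5)": _val(tiny["tiny_bivariate.csv"], "mvSampEn", cfg2),
        "mFreEn(m=2)": _val(tiny["tiny_bivariate.csv"], "mFreEn", cfg2),
    }
    manifest["entropies"]["tiny_threeband.csv"] = {
        "mFreEn(m=2)": _val(tiny["tiny_threeband.csv"], "mFreEn", cfg2),
    }

    # univariate sample-entropy cross-check input: seeded WGN, N=200
    wgn200 = white_gaussian_noise(NoiseSpec(kind="wgn", length=200, seed=child_seed(master_seed, 1)))
    series200 = MultibandSeries(wgn200)
    write_series(series200, out_dir / "wgn_univariate_200.csv")
    manifest["entropies"]["wgn_univariate_200.csv"] = {
        "mvSampEn(m=2,r=0.15sd)": _val(series200, "mvSampEn", EmbeddingConfig(m=2)),
    }

    trio = {
        "mix_1500.csv": mix_signal(
            MixParams(p=0.2, amplitude=2.0, freq_hz=10.0, seed=child_seed(master_seed, 2))
        ),
        "wgn_1500.csv": white_gaussian_noise(
            NoiseSpec(kind="wgn", length=1500, seed=child_seed(master_seed, 3))
        ),
        "pink_1500.csv": one_over_f_noise(
            NoiseSpec(kind="one_over_f", length=1500, seed=child_seed(master_seed, 4))
        ),
    }
    for name, sig in trio.items():
        write_series(MultibandSeries(sig, sample_rate_hz=500.0), out_dir / name)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
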