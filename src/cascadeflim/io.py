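"""File formats: decay CSVs, FLIM TIFF stacks, fluorophore pair tables, maps.

Conventions
-----------
- Bulk decay histograms: CSV with columns ``time_ns,counts``.
- FLIM stacks: multi-page TIFF, pages = TCSPC time bins; the bin width and
  repetition period (ns) are stored in the TIFF's shaped metadata.
- Lifetime / force maps: single-page 32-bit float TIFF.
- Fluorophore pair tables: JSON list of objects with keys
  ``donor, acceptor, tau_D_ns, R0_nm`` (optional ``kappa2``).
- All tables carry explicit unit suffixes in column names (tau_ns, K_per_s,
  R_nm, F_pN) to avoid rate-unit ambiguity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cascade import FluorophorePair
from .decay import DecayHistogram
from .errors import ConfigurationError

__all__ = [
    "read_decay_csv",
    "write_decay_csv",
    "read_flim_stack",
    "write_flim_stack",
    "read_map_tiff",
    "write_map_tiff",
    "load_pair_table",
    "save_pair_table",
]


def write_decay_csv(path, hist: DecayHistogram) -> None:
    df = pd.DataFrame({"time_ns": hist.bin_centers, "counts": hist.counts})
    df.to_csv(path, index=False)


def read_decay_csv(path, period_ns: float | None = None) -> DecayHistogram:
    """Read a time_ns,counts CSV.  If the period is not given it is taken as
    one bin width past the last bin centre (a full-period histogram)."""
    df = pd.read_csv(path)
    if not {"time_ns", "counts"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns time_ns,counts")
    centers = df["time_ns"].to_numpy(dtype=float)
    counts = df["counts"].to_numpy(dtype=float)
    width = centers[1] - centers[0]
    if period_ns is None:
        period_ns = float(centers[-1] + width / 2.0 - (centers[0] - width / 2.0))
    integral = np.allclose(counts, np.round(counts))
    return DecayHistogram(
        bin_centers=centers, counts=counts, period_ns=period_ns,
        origin_ns=float(centers[0] - width / 2.0), is_expectation=not integral,
    )


def write_flim_stack(path, stack: np.ndarray, period_ns: float) -> None:
    """Multi-page TIFF with pages = time bins; bin width recorded in metadata."""
    stack = np.asarray(stack)
    bin_width = period_ns / stack.shape[0]
    tifffile.imwrite(
        path,
        stack.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "TYX", "bin_width_ns": bin_width, "period_ns": period_ns},
    )


def read_flim_stack(path) -> tuple[np.ndarray, float]:
    """Returns (stack, period_ns)."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    period = meta.get("period_ns")
    if period is None:
        bw = meta.get("bin_width_ns")
        if bw is None:
            raise ConfigurationError(f"{path}: no period_ns/bin_width_ns metadata")
        period = bw * stack.shape[0]
    counts = np.asarray(stack, dtype=float)
    if np.allclose(counts, np.round(counts)):
        counts = np.round(counts).astype(np.int64)
    return counts, float(period)


def write_map_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_map_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def save_pair_table(path, pairs) -> None:
    if not isinstance(pairs, dict):
        pairs = {p.key: p for p in pairs}
    rows = [
        {
            "donor": p.donor,
            "acceptor": p.acceptor,
            "tau_D_ns": p.tau_D_ns,
            "R0_nm": p.R0_nm,
            "kappa2": p.kappa2,
        }
        for p in pairs.values()
    ]
    Path(path).write_text(json.dumps(rows, indent=2))


def load_pair_table(path) -> dict[tuple[str, str], FluorophorePair]:
    rows = json.loads(Path(path).read_text())
    pairs = {}
    for row in rows:
        try:
            p = FluorophorePair(
                donor=row["donor"],
                acceptor=row["acceptor"],
                tau_D_ns=float(row["tau_D_ns"]),
                R0_nm=float(row["R0_nm"]),
                kappa2=float(row.get("kappa2", 2.0 / 3.0)),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: pair entry missing key {exc}") from exc
        pairs[p.key] = p
    return pairs
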