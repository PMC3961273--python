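"""Trace/profile/call serialization and synthetic tracing data.

Traces are plain tab-separated text: one row per bead with columns
``nucleus_id, arm, bead_index, x_um, y_um, z_um`` and a commented header
carrying the parameter digest and nucleus radius.  The synthetic-profile
generator stands in for experimental 24-nucleus tracing data: per-bead
contact frequencies are drawn binomially around a baseline rate, with
elevated rates at planted attachment positions and suppressed rates at
planted anti-contact positions, providing ground truth for end-to-end
tests of the peak caller.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactProfile, PeakCall
from .ensemble import Ensemble
from .nucleus import NucleusModel
from .params import ARM_IDS, ModelParams, params_digest

__all__ = [
    "TRACE_COLUMNS",
    "TraceFormatError",
    "write_traces",
    "read_traces",
    "write_profiles",
    "read_profiles",
    "write_calls",
    "synth_profiles",
    "default_band_map",
    "annotate_calls",
]

TRACE_COLUMNS = ["nucleus_id", "arm", "bead_index", "x_um", "y_um", "z_um"]

#: Global cytological division ranges of the 100-division polytene map.
ARM_DIVISIONS = {"X": (1, 20), "2L": (21, 40), "2R": (41, 60), "3L": (61, 80), "3R": (81, 100)}


class TraceFormatError(ValueError):
    """Malformed trace/profile file; message carries the offending line."""


def _open_sink(sink):
    if isinstance(sink, (str, Path)):
        return open(sink, "w"), True
    return sink, False


def write_traces(ensemble: Ensemble, sink, params: ModelParams | None = None) -> None:
    """Write an ensemble as a TSV trace file (1e-6 um precision)."""
    fh, close = _open_sink(sink)
    try:
        fh.write(f"#params={ensemble.params_digest}\n")
        if params is not None:
            fh.write(f"#nucleus_radius={params.nucleus_radius:.6f}\n")
        for nuc in ensemble.nuclei:
            cc = nuc.chromocenter
            fh.write(
                f"#nucleus\t{nuc.nucleus_id}\tarrangement={nuc.arrangement_id}"
                f"\tseed={nuc.rng_seed}"
                f"\tchromocenter={cc[0]:.6f},{cc[1]:.6f},{cc[2]:.6f}\n"
            )
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for nuc in ensemble.nuclei:
            for arm in ARM_IDS:
                for i, (x, y, z) in enumerate(nuc.chains[arm]):
                    fh.write(f"{nuc.nucleus_id}\t{arm}\t{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
    finally:
        if close:
            fh.close()


def read_traces(source) -> Ensemble:
    """Read a trace file back into an ensemble.

    Coordinates round-trip at 1e-6 um.  Malformed rows raise
    :class:`TraceFormatError` naming the line number; a params-digest
    mismatch between header and recomputed digest is not checked here (the
    digest is provenance only).
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = source.read().splitlines()
    digest = ""
    nuc_meta: dict[str, dict] = {}
    rows = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#nucleus\t"):
            parts = line.split("\t")
            meta = {"id": parts[1]}
            for item in parts[2:]:
                k, _, v = item.partition("=")
                meta[k] = v
            nuc_meta[parts[1]] = meta
            continue
        if line.startswith("#params="):
            digest = line.split("=", 1)[1].strip()
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if not header_seen:
            if parts != TRACE_COLUMNS:
                raise TraceFormatError(
                    f"line {lineno}: expected header {TRACE_COLUMNS}, got {parts}"
                )
            header_seen = True
            continue
        if len(parts) != len(TRACE_COLUMNS):
            raise TraceFormatError(
                f"line {lineno}: expected {len(TRACE_COLUMNS)} columns, got {len(parts)}"
            )
        try:
            rows.append(
                (parts[0], parts[1], int(parts[2]), float(parts[3]), float(parts[4]), float(parts[5]))
            )
        except ValueError as err:
            raise TraceFormatError(f"line {lineno}: {err}") from err
    if not rows:
        raise TraceFormatError("no trace rows found")
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    nuclei = []
    for nid, sub in df.groupby("nucleus_id", sort=False):
        chains = {}
        for arm, armsub in sub.groupby("arm", sort=False):
            armsub = armsub.sort_values("bead_index")
            idx = armsub["bead_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise TraceFormatError(
                    f"nucleus {nid} arm {arm}: bead_index not contiguous from 0"
                )
            chains[arm] = armsub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        missing = set(ARM_IDS) - set(chains)
        if missing:
            raise TraceFormatError(f"nucleus {nid}: missing arms {sorted(missing)}")
        meta = nuc_meta.get(nid, {})
        cc = meta.get("chromocenter", "")
        chromocenter = (
            np.array([float(v) for v in cc.split(",")]) if cc else np.zeros(3)
        )
        nuclei.append(
            NucleusModel(
                params_digest=digest,
                chromocenter=chromocenter,
                arrangement_id=meta.get("arrangement", ""),
                chains={a: chains[a] for a in ARM_IDS},
                rng_seed=int(meta.get("seed", 0) or 0),
                nucleus_id=str(nid),
            )
        )
    return Ensemble(nuclei=nuclei, params_digest=digest)


# ---------------------------------------------------------------------------
# profiles and calls
# ---------------------------------------------------------------------------


def write_profiles(profiles: Mapping[str, ContactProfile] | Sequence[ContactProfile], sink) -> None:
    """Write contact profiles as a TSV (arm, bead_index, contour_um, frequency)."""
    if isinstance(profiles, Mapping):
        items = [profiles[a] for a in ARM_IDS if a in profiles]
    else:
        items = list(profiles)
    fh, close = _open_sink(sink)
    try:
        fh.write("arm\tbead_index\tcontour_um\tfrequency\tn_nuclei\n")
        for prof in items:
            for i, (c, f) in enumerate(zip(prof.contour_positions, prof.frequencies)):
                fh.write(f"{prof.arm_id}\t{i}\t{c:.6f}\t{f:.10g}\t{prof.n_nuclei}\n")
    finally:
        if close:
            fh.close()


def read_profiles(source) -> dict[str, ContactProfile]:
    df = pd.read_csv(source, sep="\t")
    needed = {"arm", "bead_index", "contour_um", "frequency", "n_nuclei"}
    if not needed <= set(df.columns):
        raise TraceFormatError(f"profile file missing columns {sorted(needed - set(df.columns))}")
    out = {}
    for arm, sub in df.groupby("arm", sort=False):
        sub = sub.sort_values("bead_index")
        out[str(arm)] = ContactProfile(
            arm_id=str(arm),
            frequencies=sub["frequency"].to_numpy(float),
            n_nuclei=int(sub["n_nuclei"].iloc[0]),
            contour_positions=sub["contour_um"].to_numpy(float),
        )
    return out


def write_calls(calls: Sequence[PeakCall], sink, bands: Mapping | None = None) -> None:
    df = annotate_calls(calls, bands) if bands else pd.DataFrame(
        [
            {
                "arm": c.arm_id,
                "bead_index": c.bead_index,
                "contour_um": c.contour_position,
                "frequency": c.frequency,
                "call_type": c.call_type,
            }
            for c in calls
        ],
        columns=["arm", "bead_index", "contour_um", "frequency", "call_type"],
    )
    if isinstance(sink, (str, Path)):
        df.to_csv(sink, sep="\t", index=False)
    else:
        df.to_csv(sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# synthetic tracing experiments with planted ground truth
# ---------------------------------------------------------------------------


def synth_profiles(
    params: ModelParams,
    baseline_p: float,
    planted_contacts: Sequence[tuple] = (),
    planted_anti: Sequence[tuple] = (),
    n_nuclei: int | None = None,
    rng=None,
) -> dict[str, ContactProfile]:
    """Synthetic per-arm contact profiles with planted signal.

    Per-bead frequencies are Binomial(n_nuclei, p) / n_nuclei draws with
    ``p = baseline_p`` everywhere except the planted positions, where the
    provided elevated (contacts) or suppressed (anti-contacts) rates are
    used.  Planted entries are ``(arm_id, bead_index, rate)``.
    """
    if not (0.0 <= baseline_p <= 1.0):
        raise ValueError("baseline_p must be in [0, 1]")
    if n_nuclei is None:
        n_nuclei = params.nuclei_per_experiment
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rates = {a: np.full(params.arm_count(a), baseline_p) for a in ARM_IDS}
    for arm, bead, p in list(planted_contacts) + list(planted_anti):
        if arm not in rates:
            raise ValueError(f"unknown arm {arm!r}")
        if not (0 <= bead < len(rates[arm])):
            raise ValueError(f"planted bead {bead} outside arm {arm}")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"planted rate {p} not a probability")
        rates[arm][bead] = p
    out = {}
    for a in ARM_IDS:
        counts = rng.binomial(n_nuclei, rates[a])
        out[a] = ContactProfile(
            arm_id=a,
            frequencies=counts / n_nuclei,
            n_nuclei=n_nuclei,
            contour_positions=np.arange(params.arm_count(a)) * params.bond_length,
        )
    return out


# ---------------------------------------------------------------------------
# cytological band map
# ---------------------------------------------------------------------------


def default_band_map(params: ModelParams) -> dict[str, list[tuple[str, tuple[int, int]]]]:
    """Uniform division of each arm's beads among its 20 cytological
    divisions of the 100-division polytene nomenclature (X: 1-20,
    2L: 21-40, 2R: 41-60, 3L: 61-80, 3R: 81-100).

    Ranges are half-open bead-index intervals ``(start, stop)`` that
    partition the arm.
    """
    out = {}
    for arm in ARM_IDS:
        n = params.arm_count(arm)
        lo, hi = ARM_DIVISIONS[arm]
        n_div = hi - lo + 1
        edges = np.linspace(0, n, n_div + 1).round().astype(int)
        out[arm] = [
            (str(lo + i), (int(edges[i]), int(edges[i + 1])))
            for i in range(n_div)
            if edges[i + 1] > edges[i]
        ]
    return out


def annotate_calls(calls: Sequence[PeakCall], bands: Mapping | None) -> pd.DataFrame:
    """Table of calls augmented with their cytological division label."""
    rows = []
    for c in calls:
        label = ""
        if bands is not None:
            if c.arm_id not in bands:
                raise ValueError(f"band map does not cover arm {c.arm_id}")
            for lab, (start, stop) in bands[c.arm_id]:
                if start <= c.bead_index < stop:
                    label = lab
                    break
            else:
                raise ValueError(
                    f"bead {c.bead_index} of arm {c.arm_id} outside band coverage"
                )
        rows.append(
            {
                "arm": c.arm_id,
                "bead_index": c.bead_index,
                "contour_um": c.contour_position,
                "frequency": c.frequency,
                "call_type": c.call_type,
                "division": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["arm", "bead_index", "contour_um", "frequency", "call_type", "division"],
    )
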