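"""Raw-acquisition preprocessing: bead normalization, singlet gating,
barcode deconvolution, spillover compensation and arcsinh transformation.

Order of operations in :func:`preprocess_pipeline` is fixed as
normalize -> gate -> debarcode -> compensate -> transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .fcs_io import EventTable, ValidationError, SIGNAL_ROLES

__all__ = [
    "GatingConfig",
    "BarcodeScheme",
    "SpilloverMatrix",
    "TransformConfig",
    "normalize_beads",
    "gate_singlets",
    "estimate_barcode_thresholds",
    "debarcode",
    "estimate_spillover",
    "compensate",
    "transform_arcsinh",
    "preprocess_pipeline",
]


@dataclass
class GatingConfig:
    """Thresholds for bead identification, DNA/event-length singlet gating
    and time-interval bead normalization."""

    dna_channels: tuple = ("191Ir", "193Ir")
    dna_low: float = 3.5          # arcsinh scale
    dna_high: float = 7.5
    event_length_range: tuple = (10, 150)
    bead_channels: list = field(default_factory=list)
    bead_interval_seconds: float = 100.0
    min_beads_per_interval: int = 50
    cofactor: float = 5.0
    per_channel_factors: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.event_length_range
        if not lo < hi:
            raise ValidationError("event_length_range must satisfy min < max")
        if self.bead_interval_seconds <= 0:
            raise ValidationError("bead_interval_seconds must be > 0")
        if self.min_beads_per_interval <= 0:
            raise ValidationError("min_beads_per_interval must be > 0")


@dataclass
class BarcodeScheme:
    """Sample-to-binary-code map over the barcode channels."""

    barcode_channels: list
    codes: dict
    min_hamming: int = 2

    def __post_init__(self) -> None:
        n = len(self.barcode_channels)
        self.codes = {k: np.asarray(v, int) for k, v in self.codes.items()}
        for sid, code in self.codes.items():
            if len(code) != n:
                raise ValidationError(f"code for {sid!r} has wrong length")
        keys = list(self.codes)
        seen = {}
        for sid in keys:
            t = tuple(self.codes[sid])
            if t in seen:
                raise ValidationError(
                    f"duplicate barcode code for {seen[t]!r} and {sid!r}"
                )
            seen[t] = sid
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = int(np.sum(self.codes[a] != self.codes[b]))
                if d < self.min_hamming:
                    raise ValidationError(
                        f"codes for {a!r} and {b!r} have Hamming distance {d} "
                        f"< min_hamming {self.min_hamming}"
                    )


@dataclass
class SpilloverMatrix:
    """Square mixing matrix: row = source channel, column = receiver."""

    channels: list
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, float)
        n = len(self.channels)
        if self.S.shape != (n, n):
            raise ValidationError(
                f"spillover matrix shape {self.S.shape} does not match "
                f"{n} channels"
            )
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValidationError("spillover diagonal must be 1")
        off = self.S - np.diag(np.diag(self.S))
        if off.min() < 0 or off.max() >= 1:
            raise ValidationError("off-diagonal spillover must lie in [0, 1)")
        if (self.S.sum(axis=1)).max() >= 2:
            raise ValidationError("row-wise spill sums must be < 2")


@dataclass
class TransformConfig:
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ValidationError("cofactor must be > 0")


# ---------------------------------------------------------------------------
# bead identification and normalization
# ---------------------------------------------------------------------------

def _bead_mask(table: EventTable, gating: GatingConfig) -> np.ndarray:
    """Bead events: bright on every bead channel and DNA-negative."""
    bead_names = gating.bead_channels or table.names_for_role("bead")
    if not bead_names:
        raise ValidationError("no bead channels configured or present")
    cf = gating.cofactor
    floor = 2.0  # arcsinh scale; ~27 counts at cofactor 5
    mask = np.ones(table.n_events, bool)
    for name in bead_names:
        v = np.arcsinh(table.column(name) / cf)
        cut, _ = _split_1d(v)
        low = v[v <= cut]
        if low.size and low.mean() > floor:
            # channel is bright everywhere (e.g. a beads-only table): the
            # two-class split would halve the bead population
            cut = floor
        mask &= v > cut
    for name in gating.dna_channels:
        if name in table.channel_names:
            mask &= np.arcsinh(table.column(name) / cf) < gating.dna_low
    return mask


def normalize_beads(table: EventTable, gating: GatingConfig):
    """Correct acquisition drift using EQ-bead medians per time interval.

    Per interval of ``bead_interval_seconds``, a scalar correction factor
    (global median bead intensity over interval median, averaged across
    bead channels on the count scale) is computed, linearly interpolated at
    interval midpoints and applied to all signal channels. Events falling
    in intervals with fewer than ``min_beads_per_interval`` beads are
    dropped and reported.
    """
    if table.transformed:
        raise ValidationError("normalize_beads expects untransformed counts")
    beads = _bead_mask(table, gating)
    if not beads.any():
        raise ValidationError(
            "no bead events identified; check the configured bead channels"
        )
    bead_names = gating.bead_channels or table.names_for_role("bead")
    t = table.time
    t0 = float(t.min()) if t.size else 0.0
    width = gating.bead_interval_seconds
    n_int = max(1, int(np.ceil((float(t.max()) - t0) / width))) if t.size else 1
    interval = np.minimum(((t - t0) / width).astype(int), n_int - 1)

    bead_vals = table.matrix(bead_names)[beads]
    bead_int = interval[beads]
    global_med = np.median(bead_vals, axis=0)

    rows = []
    mids, factors = [], []
    for i in range(n_int):
        in_i = bead_int == i
        n_b = int(in_i.sum())
        ok = n_b >= gating.min_beads_per_interval
        if n_b:
            med = np.median(bead_vals[in_i], axis=0)
            per_chan = np.divide(global_med, med, out=np.ones_like(med), where=med > 0)
            fac = float(per_chan.mean())
        else:
            per_chan = np.ones_like(global_med)
            fac = np.nan
        rows.append(
            {
                "interval": i,
                "t_start": t0 + i * width,
                "t_mid": t0 + (i + 0.5) * width,
                "n_beads": n_b,
                "factor": fac,
                "excluded": not ok,
            }
        )
        if ok:
            mids.append(t0 + (i + 0.5) * width)
            factors.append(
                per_chan if gating.per_channel_factors else np.full_like(per_chan, fac)
            )
    report = pd.DataFrame(rows)
    if not mids:
        raise ValidationError(
            "no interval reached min_beads_per_interval; cannot normalize"
        )

    mids_a = np.asarray(mids)
    fac_a = np.vstack(factors)  # kept intervals x bead channels
    keep = ~report.set_index("interval")["excluded"].to_numpy()[interval]

    out = table.copy()
    sig_idx = out.indices_for_role(*SIGNAL_ROLES)
    scalar = np.interp(t, mids_a, fac_a.mean(axis=1))
    out.values[:, sig_idx] *= scalar[:, None]
    if gating.per_channel_factors:
        # refine bead channels with their own factors (measured only there)
        for j, name in enumerate(bead_names):
            col = out.channel_index(name)
            out.values[:, col] /= scalar
            out.values[:, col] *= np.interp(t, mids_a, fac_a[:, j])
    out = out.take_events(np.flatnonzero(keep))
    report.attrs["n_dropped_events"] = int((~keep).sum())
    return out, report


def gate_singlets(table: EventTable, gating: GatingConfig) -> EventTable:
    """Keep DNA-positive, in-gate-length, non-bead events."""
    cf = gating.cofactor
    keep = np.ones(table.n_events, bool)
    for name in gating.dna_channels:
        v = np.arcsinh(table.column(name) / cf)
        keep &= (v >= gating.dna_low) & (v <= gating.dna_high)
    el_names = table.names_for_role("event_length")
    if el_names:
        el = table.column(el_names[0])
        lo, hi = gating.event_length_range
        keep &= (el >= lo) & (el <= hi)
    try:
        keep &= ~_bead_mask(table, gating)
    except ValidationError:
        pass  # no bead channels: nothing to remove
    if not keep.any():
        warnings.warn("gate_singlets removed every event", stacklevel=2)
    return table.take_events(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# debarcoding
# ---------------------------------------------------------------------------

def _split_1d(x: np.ndarray) -> tuple[float, float]:
    """Exact 2-class 1-D k-means split (minimum within-class variance).

    Returns (cutoff, simplified silhouette of the split). The cutoff is the
    midpoint between the two class means.
    """
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    if n < 2 or xs[0] == xs[-1]:
        return float(xs[0]) if n else 0.0, 0.0
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    k = np.arange(1, n)  # left class size
    lsum, lsq = csum[:-1], csq[:-1]
    rsum, rsq = csum[-1] - lsum, csq[-1] - lsq
    within = (lsq - lsum**2 / k) + (rsq - rsum**2 / (n - k))
    best = int(np.argmin(within))
    mu_l = lsum[best] / (best + 1)
    mu_r = (csum[-1] - lsum[best]) / (n - best - 1)
    cut = 0.5 * (mu_l + mu_r)
    # simplified silhouette with centroid distances
    lab = xs > cut
    a = np.where(lab, np.abs(xs - mu_r), np.abs(xs - mu_l))
    b = np.where(lab, np.abs(xs - mu_l), np.abs(xs - mu_r))
    denom = np.maximum(np.maximum(a, b), 1e-300)
    sil = float(np.mean((b - a) / denom))
    return float(cut), sil


def estimate_barcode_thresholds(
    table: EventTable, scheme: BarcodeScheme, cofactor: float = 5.0
) -> dict:
    """Per-barcode-channel on/off cutoffs on the arcsinh scale, by exact
    two-class 1-D k-means. Channels whose two-way split looks unimodal
    (simplified silhouette < 0.2) trigger a warning."""
    # pooled cutoff across all barcode channels: bimodal whenever events
    # carry both on and off barcode signal; used to rescue channels that are
    # "on" (or "off") in essentially every sample and so have no two-class
    # structure of their own
    pooled = np.arcsinh(table.matrix(scheme.barcode_channels).ravel() / cofactor)
    pooled_cut, pooled_sil = _split_1d(pooled)

    cutoffs = {}
    for name in scheme.barcode_channels:
        v = np.arcsinh(table.column(name) / cofactor)
        cut, sil = _split_1d(v)
        if sil < 0.2:
            warnings.warn(
                f"barcode channel {name!r} looks unimodal (silhouette {sil:.2f})",
                stacklevel=2,
            )
        if v.size and pooled_sil >= 0.2:
            lo, hi = v[v <= cut], v[v > cut]
            single_state = (lo.size and lo.mean() > pooled_cut) or (
                hi.size and hi.mean() < pooled_cut
            )
            if single_state or sil < 0.2:
                cut = pooled_cut
        cutoffs[name] = cut
    return cutoffs


def debarcode(
    table: EventTable,
    scheme: BarcodeScheme,
    cutoffs: dict,
    cofactor: float = 5.0,
    min_separation: float = 0.3,
):
    """Assign each event to the sample whose code matches its on/off pattern.

    Events matching no code, or failing the separation filter (lowest "on"
    arcsinh intensity minus highest "off" must exceed ``min_separation``),
    stay unassigned. Returns (assignment array with '' for unassigned,
    yield report DataFrame).
    """
    missing = [c for c in scheme.barcode_channels if c not in cutoffs]
    if missing:
        raise ValidationError(f"no cutoffs for barcode channels: {missing}")
    V = np.arcsinh(table.matrix(scheme.barcode_channels) / cofactor)
    cuts = np.array([cutoffs[c] for c in scheme.barcode_channels])
    on = V > cuts

    code_map = {tuple(code): sid for sid, code in scheme.codes.items()}
    assignment = np.empty(table.n_events, dtype=object)
    assignment[:] = ""
    patterns = on.astype(int)
    # vectorized lookup via fixed-radix encoding of the binary pattern
    radix = 1 << np.arange(len(scheme.barcode_channels))
    enc = patterns @ radix
    enc_map = {int(np.array(c) @ radix): sid for c, sid in code_map.items()}
    for code_enc, sid in enc_map.items():
        assignment[enc == code_enc] = sid

    if min_separation > 0:
        lowest_on = np.where(on, V, np.inf).min(axis=1)
        highest_off = np.where(~on, V, -np.inf).max(axis=1)
        sep = lowest_on - highest_off  # inf when all-on or all-off
        bad = np.isfinite(sep) & (sep <= min_separation)
        assignment[bad] = ""

    assigned = assignment != ""
    rows = [
        {
            "sample_id": sid,
            "n_assigned": int((assignment == sid).sum()),
        }
        for sid in scheme.codes
    ]
    report = pd.DataFrame(rows)
    report["yield"] = report["n_assigned"] / max(table.n_events, 1)
    report.attrs["n_unassigned"] = int((~assigned).sum())
    return assignment, report


# ---------------------------------------------------------------------------
# spillover
# ---------------------------------------------------------------------------

def estimate_spillover(single_stained: dict) -> SpilloverMatrix:
    """Estimate spillover from single-stained bead tables.

    ``single_stained`` maps each channel name to an EventTable of beads
    stained only for that channel. S[i][j] = median signal in channel j over
    median signal in channel i, clipped to [0, 1); unit diagonal.
    """
    channels = list(single_stained)
    n = len(channels)
    S = np.eye(n)
    for i, ci in enumerate(channels):
        tab = single_stained[ci]
        med_i = float(np.median(tab.column(ci)))
        if med_i <= 0:
            raise ValidationError(f"stained channel {ci!r} has median <= 0")
        for j, cj in enumerate(channels):
            if i == j:
                continue
            ratio = float(np.median(tab.column(cj))) / med_i
            S[i, j] = min(max(ratio, 0.0), np.nextafter(1.0, 0.0))
    return SpilloverMatrix(channels=channels, S=S)


def compensate(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Undo spillover by per-event non-negative least squares.

    Solves min ||x S - observed||^2 with x >= 0 per event over the spillover
    channels; other channels pass through unchanged. Events whose plain
    linear solve is already non-negative skip the NNLS call.
    """
    if table.transformed:
        raise ValidationError("compensation must run on untransformed counts")
    missing = [c for c in spill.channels if c not in table.channel_names]
    if missing:
        raise ValidationError(f"spillover channels not in table: {missing}")
    S = spill.S
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValidationError("spillover matrix is singular")

    idx = np.array([table.channel_index(c) for c in spill.channels])
    obs = table.values[:, idx]
    x = np.linalg.solve(S.T, obs.T).T  # x S = obs
    neg = np.flatnonzero((x < -1e-12).any(axis=1))
    ST = np.ascontiguousarray(S.T)
    for i in neg:
        x[i], _ = nnls(ST, obs[i])
    np.clip(x, 0.0, None, out=x)
    out = table.copy()
    out.values[:, idx] = x
    return out


def transform_arcsinh(table: EventTable, cfg: TransformConfig | None = None) -> EventTable:
    """arcsinh(v / cofactor) on all signal channels; time and event length
    are untouched. Refuses to run twice."""
    if table.transformed:
        raise ValidationError("table is already transformed")
    cfg = cfg or TransformConfig()
    out = table.copy()
    idx = out.indices_for_role(*SIGNAL_ROLES)
    out.values[:, idx] = np.arcsinh(out.values[:, idx] / cfg.cofactor)
    out.transformed = True
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    table: EventTable,
    gating: GatingConfig,
    scheme: BarcodeScheme,
    spill: SpilloverMatrix | None = None,
    transform: TransformConfig | None = None,
):
    """normalize -> gate -> debarcode -> compensate -> transform.

    Returns (dict sample_id -> transformed EventTable, provenance dict).
    The provenance dict accounts for every input event exactly once across
    {assigned, unassigned, excluded_by_gate, excluded_interval, bead}.
    """
    n_input = table.n_events
    normalized, bead_report = normalize_beads(table, gating)
    n_bead = int(_bead_mask(normalized, gating).sum())
    gated = gate_singlets(normalized, gating)
    n_gate_excluded = normalized.n_events - gated.n_events - n_bead

    cutoffs = estimate_barcode_thresholds(gated, scheme, gating.cofactor)
    assignment, yield_report = debarcode(gated, scheme, cutoffs, gating.cofactor)

    compensated = compensate(gated, spill) if spill is not None else gated
    transformed = transform_arcsinh(compensated, transform)

    per_sample = {}
    for sid in scheme.codes:
        sel = np.flatnonzero(assignment == sid)
        per_sample[sid] = transformed.take_events(sel)

    provenance = {
        "n_input": n_input,
        "n_excluded_interval": int(bead_report.attrs["n_dropped_events"]),
        "n_bead": n_bead,
        "n_excluded_by_gate": n_gate_excluded,
        "n_unassigned": int(yield_report.attrs["n_unassigned"]),
        "n_assigned": int(sum(t.n_events for t in per_sample.values())),
        "barcode_cutoffs": {k: float(v) for k, v in cutoffs.items()},
        "cofactor": gating.cofactor,
    }
    return per_sample, provenance
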