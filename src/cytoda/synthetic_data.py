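"""Ground-truth simulation of pooled, barcoded mass-cytometry acquisitions.

Generates a multiplexed experiment — cells from many barcoded samples,
calibration-bead events, doublets, sensitivity drift over acquisition time
and channel spillover — together with the per-event truth needed to score
every downstream pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .fcs_io import ChannelInfo, EventTable, PanelDefinition, ValidationError
from .preprocess import BarcodeScheme, SpilloverMatrix

__all__ = [
    "PopulationSpec",
    "SampleSpec",
    "DriftProfile",
    "SimulationTruth",
    "SimulationResult",
    "simulate_experiment",
    "spike_differential",
    "default_codes",
    "default_truth",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Marker-expression profile of one cell population.

    Positive markers follow a lognormal with the given median and CV on the
    ion-count scale; negative markers are zero-inflated near-zero lognormals.
    """

    name: str
    marker_medians: np.ndarray
    marker_cv: np.ndarray
    positivity_mask: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("marker_medians", "marker_cv", "positivity_mask"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr)))
        if np.any(self.marker_medians < 0):
            raise ValidationError(f"population {self.name}: medians must be >= 0")
        if np.any(self.marker_cv <= 0):
            raise ValidationError(f"population {self.name}: CV must be > 0")
        n = len(self.marker_medians)
        if len(self.marker_cv) != n or len(self.positivity_mask) != n:
            raise ValidationError(f"population {self.name}: field lengths differ")


@dataclass(frozen=True)
class SampleSpec:
    """One multiplexed sample: group label, barcode code and composition."""

    sample_id: str
    group: str
    barcode_code: np.ndarray
    population_proportions: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcode_code", np.asarray(self.barcode_code, int))
        object.__setattr__(
            self, "population_proportions", np.asarray(self.population_proportions, float)
        )
        p = self.population_proportions
        if p.size and abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"sample {self.sample_id}: proportions sum to {p.sum()}, not 1"
            )
        if p.size and p.min() < 0:
            raise ValidationError(f"sample {self.sample_id}: negative proportion")
        if self.n_events <= 0:
            raise ValidationError(f"sample {self.sample_id}: n_events must be > 0")


@dataclass(frozen=True)
class DriftProfile:
    """Piecewise-linear sensitivity multiplier over run-time fraction."""

    breakpoints: tuple = (0.0, 1.0)
    multipliers: tuple = (1.0, 0.7)

    def __post_init__(self) -> None:
        if min(self.multipliers) <= 0:
            raise ValidationError("drift multipliers must be > 0")
        if len(self.breakpoints) != len(self.multipliers):
            raise ValidationError("drift breakpoints/multipliers length mismatch")

    def __call__(self, t: np.ndarray, duration: float) -> np.ndarray:
        frac = np.asarray(t, float) / duration if duration > 0 else np.zeros_like(t)
        return np.interp(frac, self.breakpoints, self.multipliers)


FLAT_DRIFT = DriftProfile(multipliers=(1.0, 1.0))


@dataclass
class SimulationTruth:
    """Complete generating description of one pooled acquisition."""

    samples: list[SampleSpec]
    populations: list[PopulationSpec]
    panel: PanelDefinition
    barcode_channels: list[str]
    spillover_used: SpilloverMatrix | None = None
    drift_profile: DriftProfile = field(default_factory=DriftProfile)
    spiked_effects: list[tuple[str, str, float]] = field(default_factory=list)
    doublet_fraction: float = 0.02
    bead_fraction: float = 0.02
    run_duration: float = 600.0
    barcode_on_median: float = 200.0
    barcode_off_median: float = 1.0
    barcode_cv: float = 0.5
    dna_median: float = 300.0
    dna_cv: float = 0.3
    bead_median: float = 500.0
    bead_cv: float = 0.1
    background_median: float = 0.3
    dropout: float = 0.3
    cell_event_length: tuple = (15, 60)
    bead_event_length: tuple = (10, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_fraction < 1:
            raise ValidationError("doublet_fraction must be in [0, 1)")
        pop_names = {p.name for p in self.populations}
        for pop, _, _ in self.spiked_effects:
            if pop not in pop_names:
                raise ValidationError(f"spiked population {pop!r} does not exist")
        n_bc = len(self.barcode_channels)
        for s in self.samples:
            if len(s.barcode_code) != n_bc:
                raise ValidationError(
                    f"sample {s.sample_id}: code length {len(s.barcode_code)} "
                    f"!= {n_bc} barcode channels"
                )
            if len(s.population_proportions) != len(self.populations):
                raise ValidationError(
                    f"sample {s.sample_id}: proportions do not match populations"
                )

    @property
    def marker_channels(self) -> list[str]:
        return self.panel.names_for_role("marker")

    @property
    def bead_channels(self) -> list[str]:
        return self.panel.names_for_role("bead")

    @property
    def dna_channels(self) -> list[str]:
        return self.panel.names_for_role("dna")

    def barcode_scheme(self) -> BarcodeScheme:
        codes = {s.sample_id: s.barcode_code for s in self.samples}
        min_h = _min_pairwise_hamming(list(codes.values()))
        return BarcodeScheme(
            barcode_channels=list(self.barcode_channels),
            codes=codes,
            min_hamming=min(2, min_h) if codes else 2,
        )

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "run_duration": self.run_duration,
            "doublet_fraction": self.doublet_fraction,
            "bead_fraction": self.bead_fraction,
            "drift": {
                "breakpoints": list(self.drift_profile.breakpoints),
                "multipliers": list(self.drift_profile.multipliers),
            },
            "spiked_effects": [list(e) for e in self.spiked_effects],
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "barcode_code": s.barcode_code.tolist(),
                    "population_proportions": s.population_proportions.tolist(),
                    "n_events": s.n_events,
                }
                for s in self.samples
            ],
            "populations": [
                {
                    "name": p.name,
                    "marker_medians": p.marker_medians.tolist(),
                    "marker_cv": p.marker_cv.tolist(),
                    "positivity_mask": p.positivity_mask.astype(int).tolist(),
                }
                for p in self.populations
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _min_pairwise_hamming(codes: list[np.ndarray]) -> int:
    if len(codes) < 2:
        return 2
    return min(
        int(np.sum(a != b)) for a, b in combinations(codes, 2)
    )


@dataclass
class SimulationResult:
    """Pooled acquisition plus the per-event generating truth.

    ``clean_signal`` holds the signal-channel values after drift but before
    spillover mixing, for scoring compensation recovery.
    """

    table: EventTable
    per_event_truth: pd.DataFrame
    clean_signal: np.ndarray
    signal_channels: list[str]


def _lognormal(rng: np.random.Generator, median, cv, size) -> np.ndarray:
    sigma = np.sqrt(np.log1p(np.asarray(cv, float) ** 2))
    return np.asarray(median, float) * np.exp(sigma * rng.standard_normal(size))


def simulate_experiment(truth: SimulationTruth) -> SimulationResult:
    """Generate the pooled, time-sorted event table for ``truth``.

    Event order is acquisition-time order; all randomness comes from
    ``truth.seed`` so repeated calls are bit-identical.
    """
    rng = np.random.default_rng(truth.seed)
    markers = truth.marker_channels
    n_mk = len(markers)
    bc, bd, dna = truth.barcode_channels, truth.bead_channels, truth.dna_channels

    cell_rows: list[np.ndarray] = []
    cell_sample: list[str] = []
    cell_pop: list[str] = []

    pop_names = [p.name for p in truth.populations]
    for s in truth.samples:
        if not truth.populations:
            raise ValidationError(
                f"sample {s.sample_id}: no populations to draw events from"
            )
        labels = rng.choice(len(pop_names), size=s.n_events, p=s.population_proportions)
        mk = np.zeros((s.n_events, n_mk))
        for k, pop in enumerate(truth.populations):
            idx = np.flatnonzero(labels == k)
            if idx.size == 0:
                continue
            vals = _lognormal(rng, pop.marker_medians, pop.marker_cv, (idx.size, n_mk))
            neg = ~pop.positivity_mask.astype(bool)
            if neg.any() and truth.dropout > 0:
                drop = rng.random((idx.size, neg.sum())) < truth.dropout
                sub = vals[:, neg]
                sub[drop] = 0.0
                vals[:, neg] = sub
            mk[idx] = vals
        # barcode block: on-code channels bright, off-code channels dim
        bcv = np.empty((s.n_events, len(bc)))
        for j, on in enumerate(s.barcode_code):
            med = truth.barcode_on_median if on else truth.barcode_off_median
            bcv[:, j] = _lognormal(rng, med, truth.barcode_cv, s.n_events)
        dnav = _lognormal(rng, truth.dna_median, truth.dna_cv, (s.n_events, len(dna)))
        bdv = _lognormal(rng, truth.background_median, 1.0, (s.n_events, len(bd)))
        elen = rng.integers(
            truth.cell_event_length[0], truth.cell_event_length[1] + 1, s.n_events
        ).astype(float)
        cell_rows.append(np.column_stack([mk, bcv, bdv, dnav, elen]))
        cell_sample += [s.sample_id] * s.n_events
        cell_pop += [pop_names[k] for k in labels]

    if cell_rows:
        cells = np.concatenate(cell_rows, axis=0)
    else:
        cells = np.zeros((0, n_mk + len(bc) + len(bd) + len(dna) + 1))
    n_cells = cells.shape[0]

    # doublets: channel-wise sum of two random cells; event length adds too
    n_doub = int(round(truth.doublet_fraction * n_cells))
    if n_doub:
        i1 = rng.integers(0, n_cells, n_doub)
        i2 = rng.integers(0, n_cells, n_doub)
        doublets = cells[i1] + cells[i2]
    else:
        doublets = np.zeros((0, cells.shape[1]))
        i1 = np.array([], dtype=int)

    # beads: bright on every bead channel, DNA-negative, no barcode signal
    n_beads = int(round(truth.bead_fraction * max(n_cells, 1))) if n_cells else 0
    bead_block = np.zeros((n_beads, cells.shape[1]))
    if n_beads:
        off = 0
        bead_block[:, off : off + n_mk] = _lognormal(
            rng, truth.background_median, 1.0, (n_beads, n_mk)
        )
        off += n_mk
        bead_block[:, off : off + len(bc)] = _lognormal(
            rng, truth.background_median, 1.0, (n_beads, len(bc))
        )
        off += len(bc)
        bead_block[:, off : off + len(bd)] = _lognormal(
            rng, truth.bead_median, truth.bead_cv, (n_beads, len(bd))
        )
        off += len(bd)
        bead_block[:, off : off + len(dna)] = _lognormal(
            rng, truth.background_median, 1.0, (n_beads, len(dna))
        )
        bead_block[:, -1] = rng.integers(
            truth.bead_event_length[0], truth.bead_event_length[1] + 1, n_beads
        )

    all_rows = np.concatenate([cells, doublets, bead_block], axis=0)
    n_total = all_rows.shape[0]
    sample_lab = np.array(
        cell_sample + [cell_sample[i] for i in i1] + [""] * n_beads, dtype=object
    ) if n_total else np.array([], dtype=object)
    pop_lab = np.array(
        cell_pop + [cell_pop[i] for i in i1] + [""] * n_beads, dtype=object
    ) if n_total else np.array([], dtype=object)
    is_doub = np.zeros(n_total, bool)
    is_doub[n_cells : n_cells + n_doub] = True
    is_bead = np.zeros(n_total, bool)
    is_bead[n_cells + n_doub :] = True

    t = np.sort(rng.uniform(0.0, truth.run_duration, n_total))
    order = rng.permutation(n_total)  # decouple time from generation order
    all_rows, sample_lab, pop_lab = all_rows[order], sample_lab[order], pop_lab[order]
    is_doub, is_bead = is_doub[order], is_bead[order]

    n_signal = n_mk + len(bc) + len(bd) + len(dna)
    drift = truth.drift_profile(t, truth.run_duration)
    all_rows[:, :n_signal] *= drift[:, None]
    clean = all_rows[:, :n_signal].copy()

    signal_names = markers + bc + bd + dna
    if truth.spillover_used is not None:
        S = truth.spillover_used
        idx = [signal_names.index(c) for c in S.channels]
        all_rows[:, idx] = all_rows[:, idx] @ S.S

    channels = list(truth.panel.channels)
    names = [c.name for c in channels]
    # pooled column order: signal channels then event_length, then time
    col_order = signal_names + truth.panel.names_for_role("event_length")
    values = np.column_stack(
        [all_rows[:, : n_signal], all_rows[:, -1:], t]
    ) if n_total else np.zeros((0, n_signal + 2))
    ordered_channels = [channels[names.index(c)] for c in col_order]
    ordered_channels.append(ChannelInfo(metal="Time", role="time"))

    table = EventTable(values=values, channels=ordered_channels, transformed=False)
    truth_df = pd.DataFrame(
        {
            "sample_id": sample_lab,
            "population": pop_lab,
            "is_bead": is_bead,
            "is_doublet": is_doub,
            "time": t,
        }
    )
    return SimulationResult(
        table=table,
        per_event_truth=truth_df,
        clean_signal=clean,
        signal_channels=signal_names,
    )


def spike_differential(
    truth: SimulationTruth, population: str, group: str, log_odds_shift: float
) -> SimulationTruth:
    """Shift one population's abundance in one group on the log-odds scale.

    For every sample of ``group``, the target proportion p becomes
    ``expit(logit(p) + shift)`` and the remaining proportions are rescaled to
    keep the simplex. Returns a new truth; the effect is recorded in
    ``spiked_effects``.
    """
    pop_names = [p.name for p in truth.populations]
    if population not in pop_names:
        raise ValidationError(f"unknown population {population!r}")
    k = pop_names.index(population)

    new_samples = []
    for s in truth.samples:
        if s.group != group:
            new_samples.append(s)
            continue
        p = s.population_proportions.copy()
        old = p[k]
        new = 1.0 / (1.0 + np.exp(-(np.log(old / (1 - old)) + log_odds_shift)))
        rest = 1.0 - old
        if rest > 0:
            p[np.arange(len(p)) != k] *= (1.0 - new) / rest
        p[k] = new
        new_samples.append(replace(s, population_proportions=p / p.sum()))
    return replace(
        truth,
        samples=new_samples,
        spiked_effects=truth.spiked_effects + [(population, group, log_odds_shift)],
    )


# ---------------------------------------------------------------------------
# default experiment builder
# ---------------------------------------------------------------------------

def default_codes(n_samples: int, n_channels: int = 6) -> list[np.ndarray]:
    """Default codebook: all 3-of-n codes, then 4-of-n codes as needed."""
    codes = [
        np.array([1 if i in combo else 0 for i in range(n_channels)])
        for combo in combinations(range(n_channels), 3)
    ]
    codes += [
        np.array([1 if i in combo else 0 for i in range(n_channels)])
        for combo in combinations(range(n_channels), 4)
    ]
    if n_samples > len(codes):
        raise ValidationError(
            f"{n_samples} samples exceed the {len(codes)} available default codes"
        )
    return codes[:n_samples]


def build_panel(
    n_markers: int = 20, n_lineage: int = 14, n_barcode: int = 6, n_bead: int = 5
) -> PanelDefinition:
    """Generic panel: markers M01.., CD45 barcode channels, EQ bead channels,
    Ir191/Ir193 DNA and event length."""
    chans = [
        ChannelInfo(
            metal=f"M{i + 1:02d}",
            marker=f"marker{i + 1}",
            role="marker",
            use_for_lineage_clustering=i < n_lineage,
            use_for_embedding=True,
        )
        for i in range(n_markers)
    ]
    bc_metals = ["89Y", "113In", "115In", "195Pt", "196Pt", "198Pt"]
    chans += [
        ChannelInfo(metal=bc_metals[i % 6] if n_barcode <= 6 else f"BC{i}",
                    marker="CD45", role="barcode")
        for i in range(n_barcode)
    ]
    chans += [
        ChannelInfo(metal=m, marker="EQbead", role="bead")
        for m in ["140Ce", "151Eu", "153Eu", "165Ho", "175Lu"][:n_bead]
    ]
    chans += [
        ChannelInfo(metal="191Ir", marker="DNA1", role="dna"),
        ChannelInfo(metal="193Ir", marker="DNA2", role="dna"),
        ChannelInfo(metal="EventLength", role="event_length"),
    ]
    return PanelDefinition(channels=chans)


def adjacent_spillover(channels: list[str], spill: float = 0.02) -> SpilloverMatrix:
    """Spillover into the next-higher mass channel (cyclically truncated)."""
    n = len(channels)
    S = np.eye(n)
    for i in range(n - 1):
        S[i, i + 1] = spill
    return SpilloverMatrix(channels=list(channels), S=S)


def default_truth(
    n_per_group: tuple = (11, 11),
    group_names: tuple = ("CON", "MS", "CD"),
    n_events: int = 10_000,
    n_populations: int = 14,
    n_markers: int = 20,
    n_lineage: int = 14,
    spill: float = 0.02,
    drift: DriftProfile | None = None,
    seed: int = 0,
    proportion_concentration: float = 200.0,
) -> SimulationTruth:
    """Build a paper-scale two-group (optionally three-group) design."""
    rng = np.random.default_rng(seed)
    panel = build_panel(n_markers=n_markers, n_lineage=n_lineage)
    markers = panel.names_for_role("marker")
    n_mk = len(markers)

    # distinct positivity patterns over the lineage channels
    patterns: list[tuple] = []
    while len(patterns) < n_populations:
        pat = tuple(rng.random(n_mk) < 0.4)
        if not any(pat[:n_lineage]):
            continue
        if all(
            sum(a != b for a, b in zip(pat[:n_lineage], q[:n_lineage])) >= 2
            for q in patterns
        ):
            patterns.append(pat)

    populations = []
    for k, pat in enumerate(patterns):
        mask = np.array(pat, bool)
        med = np.where(mask, rng.uniform(80, 400, n_mk), rng.uniform(0.3, 1.5, n_mk))
        cv = rng.uniform(0.3, 0.6, n_mk)
        populations.append(
            PopulationSpec(
                name=f"pop{k + 1:02d}",
                marker_medians=med,
                marker_cv=cv,
                positivity_mask=mask,
            )
        )

    base = rng.dirichlet(np.full(n_populations, 5.0))
    base = np.maximum(base, 0.01)
    base /= base.sum()

    n_total = sum(n_per_group)
    codes = default_codes(n_total)
    samples = []
    i = 0
    for g, n_g in zip(group_names, n_per_group):
        for _ in range(n_g):
            props = rng.dirichlet(base * proportion_concentration)
            samples.append(
                SampleSpec(
                    sample_id=f"S{i + 1:02d}",
                    group=g,
                    barcode_code=codes[i],
                    population_proportions=props,
                    n_events=n_events,
                )
            )
            i += 1

    signal = markers + panel.names_for_role("barcode", "bead", "dna")
    return SimulationTruth(
        samples=samples,
        populations=populations,
        panel=panel,
        barcode_channels=panel.names_for_role("barcode"),
        spillover_used=adjacent_spillover(signal, spill) if spill > 0 else None,
        drift_profile=drift if drift is not None else DriftProfile(),
        seed=seed,
    )
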