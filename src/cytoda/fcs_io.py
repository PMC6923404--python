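"""Event-table container and file I/O: FCS 2.0/3.0/3.1 reading, FCS 3.1
writing, and the CSV sidecar tables (panel, barcode scheme, spillover,
sample metadata).

The FCS support here is deliberately minimal: list-mode (``$MODE L``) data
with float, double or integer storage, little- or big-endian. Channel roles
are never guessed from an FCS file alone — they come either from a panel
CSV supplied by the caller or from the vendor-extension keywords this
package writes itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "EventTable",
    "PanelDefinition",
    "SampleMetadata",
    "FcsFormatError",
    "ValidationError",
    "read_fcs",
    "write_fcs",
    "read_panel_csv",
    "read_barcode_csv",
    "read_spillover_csv",
    "read_metadata_csv",
    "read_sidecar_tables",
]

CHANNEL_ROLES = ("marker", "barcode", "bead", "dna", "event_length", "time", "other")

#: roles whose values are ion counts subject to drift/spillover/transform
SIGNAL_ROLES = ("marker", "barcode", "bead", "dna")


class FcsFormatError(ValueError):
    """Raised when a file does not parse as FCS."""


class ValidationError(ValueError):
    """Raised when a table or sidecar violates its contract."""


@dataclass(frozen=True)
class ChannelInfo:
    """Description of one acquisition channel."""

    metal: str
    marker: str = ""
    role: str = "other"
    use_for_lineage_clustering: bool = False
    use_for_embedding: bool = False

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValidationError(
                f"unknown channel role {self.role!r} for {self.metal!r}; "
                f"expected one of {CHANNEL_ROLES}"
            )
        if self.role != "marker" and (
            self.use_for_lineage_clustering or self.use_for_embedding
        ):
            raise ValidationError(
                f"channel {self.metal!r}: clustering/embedding flags are only "
                f"allowed on marker channels (role is {self.role!r})"
            )

    @property
    def name(self) -> str:
        return self.metal


@dataclass
class EventTable:
    """Events x channels matrix of ion dual counts (or transformed values).

    ``values`` holds one column per entry of ``channels`` (including the
    time channel, stored in seconds from run start). ``transformed`` flags
    whether signal channels carry arcsinh-transformed values.
    """

    values: np.ndarray
    channels: list[ChannelInfo]
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (events x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValidationError(
                f"{self.values.shape[1]} columns for {len(self.channels)} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate channel names: {dupes}")
        n_time = sum(c.role == "time" for c in self.channels)
        if n_time != 1:
            raise ValidationError(f"expected exactly one time channel, found {n_time}")
        if self.values.size:
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("non-finite values in event table")
            if not self.transformed and self.values.min() < 0:
                raise ValidationError("raw ion counts must be >= 0")

    # -- channel bookkeeping -------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def indices_for_role(self, *roles: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.role in roles], dtype=int
        )

    def names_for_role(self, *roles: str) -> list[str]:
        return [c.name for c in self.channels if c.role in roles]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    @property
    def time(self) -> np.ndarray:
        """Per-event acquisition time in seconds."""
        return self.column(self.names_for_role("time")[0])

    # -- derived tables ------------------------------------------------------

    def copy(self) -> "EventTable":
        return EventTable(self.values.copy(), list(self.channels), self.transformed)

    def take_events(self, index: np.ndarray) -> "EventTable":
        return EventTable(self.values[index], list(self.channels), self.transformed)

    def matrix(self, names: list[str]) -> np.ndarray:
        idx = [self.channel_index(n) for n in names]
        return self.values[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


@dataclass
class PanelDefinition:
    """Ordered channel descriptions for one antibody panel."""

    channels: list[ChannelInfo] = field(default_factory=list)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def names_for_role(self, *roles: str) -> list[str]:
        return [c.name for c in self.channels if c.role in roles]

    def lineage_channels(self) -> list[str]:
        return [c.name for c in self.channels if c.use_for_lineage_clustering]

    def embedding_channels(self) -> list[str]:
        return [c.name for c in self.channels if c.use_for_embedding]


@dataclass
class SampleMetadata:
    """Sample-level design table: id, group label, optional covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns or "group" not in self.table.columns:
            raise ValidationError("metadata needs 'sample_id' and 'group' columns")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            raise ValidationError(
                f"duplicate sample_id: {sorted(ids[ids.duplicated()].unique())}"
            )
        if self.table["group"].isna().any():
            raise ValidationError("every sample needs a group label")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]


# ---------------------------------------------------------------------------
# FCS reading / writing
# ---------------------------------------------------------------------------

_DELIM = "/"
# vendor-extension keywords for lossless role round-tripping
_ROLE_KEY = "CYTODAPnROLE"
_FLAGS_KEY = "CYTODAPnFLAGS"


def _escape(v: str) -> str:
    return v.replace(_DELIM, _DELIM * 2)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FcsFormatError("empty TEXT segment")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # delimiter escaping: doubled delimiter inside a value
    parts = body.split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            # empty part means an escaped delimiter inside the token
            tok += delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {tokens[j].strip(): tokens[j + 1] for j in range(0, len(tokens), 2)}


def read_fcs(path, panel: PanelDefinition | None = None) -> EventTable:
    """Read an FCS 2.0/3.0/3.1 list-mode file into an :class:`EventTable`.

    Channel roles come from ``panel`` (matched by channel name) when given;
    otherwise from this package's own extension keywords if present; the
    fallback role is ``other`` (with the time channel recognised by its
    ``$PnN`` of ``Time``). Time values are converted to seconds using
    ``$TIMESTEP`` (default 0.001 s per tick).
    """
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58 or not header[:3] == b"FCS":
            raise FcsFormatError(f"{path}: not an FCS file (bad magic)")
        version = header[:6].decode("ascii", errors="replace")
        if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
            raise FcsFormatError(f"{path}: unsupported version {version!r}")

        def _off(a: int, b: int) -> int:
            fieldtxt = header[a:b].decode("ascii").strip() or "0"
            try:
                return int(fieldtxt)
            except ValueError:
                raise FcsFormatError(
                    f"{path}: malformed header offset field {fieldtxt!r}"
                ) from None

        text_begin, text_end = _off(10, 18), _off(18, 26)
        data_begin, data_end = _off(26, 34), _off(34, 42)
        fh.seek(text_begin)
        kw = _parse_text_segment(fh.read(text_end - text_begin + 1))

        def _require(key: str) -> str:
            if key not in kw:
                raise FcsFormatError(f"{path}: missing required keyword {key}")
            return kw[key]

        n_par = int(_require("$PAR"))
        n_tot = int(_require("$TOT"))
        datatype = _require("$DATATYPE").strip().upper()
        byteord = _require("$BYTEORD").strip()
        mode = kw.get("$MODE", "L").strip().upper()
        if mode != "L":
            raise FcsFormatError(f"{path}: only list mode supported, got $MODE={mode}")
        if data_begin == 0:
            data_begin = int(kw.get("$BEGINDATA", "0"))
            data_end = int(kw.get("$ENDDATA", "0"))

        little = byteord.startswith("1")
        endian = "<" if little else ">"
        if datatype == "F":
            dtype = np.dtype(endian + "f4")
        elif datatype == "D":
            dtype = np.dtype(endian + "f8")
        elif datatype == "I":
            bits = {int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
            if bits != {32} and bits != {16}:
                raise FcsFormatError(
                    f"{path}: integer data requires uniform 16/32-bit $PnB, got {bits}"
                )
            dtype = np.dtype(endian + ("u4" if bits == {32} else "u2"))
        else:
            raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

        fh.seek(data_begin)
        n_vals = n_tot * n_par
        raw = fh.read(n_vals * dtype.itemsize)
        if len(raw) < n_vals * dtype.itemsize:
            raise FcsFormatError(f"{path}: truncated DATA segment")
        values = (
            np.frombuffer(raw, dtype=dtype, count=n_vals)
            .reshape(n_tot, n_par)
            .astype(np.float64)
        )

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    markers = [kw.get(f"$P{i}S", "") for i in range(1, n_par + 1)]

    panel_by_name = {c.name: c for c in panel.channels} if panel is not None else {}
    channels: list[ChannelInfo] = []
    for i, (name, marker) in enumerate(zip(names, markers), start=1):
        if name in panel_by_name:
            channels.append(panel_by_name[name])
            continue
        role = kw.get(f"{_ROLE_KEY[:6]}P{i}ROLE", "")
        flags = kw.get(f"{_FLAGS_KEY[:6]}P{i}FLAGS", "00")
        if role in CHANNEL_ROLES:
            channels.append(
                ChannelInfo(
                    metal=name,
                    marker=marker,
                    role=role,
                    use_for_lineage_clustering=flags[0] == "1",
                    use_for_embedding=flags[1] == "1",
                )
            )
        elif name.lower() == "time":
            channels.append(ChannelInfo(metal=name, marker=marker, role="time"))
        else:
            channels.append(ChannelInfo(metal=name, marker=marker, role="other"))

    time_idx = [i for i, c in enumerate(channels) if c.role == "time"]
    if not time_idx:
        warnings.warn(
            f"{path}: no TIME channel found; substituting event-index time",
            stacklevel=2,
        )
        channels.append(ChannelInfo(metal="Time", role="time"))
        values = np.column_stack([values, np.arange(n_tot, dtype=np.float64)])
    else:
        timestep = float(kw.get("$TIMESTEP", "0.001"))
        values = values.copy()
        values[:, time_idx[0]] *= timestep

    transformed = kw.get("CYTODATRANSFORMED", "0") == "1"
    return EventTable(values=values, channels=channels, transformed=transformed)


def write_fcs(table: EventTable, path) -> None:
    """Write ``table`` as a single-dataset FCS 3.1 file (float32 data).

    Time is written in seconds with ``$TIMESTEP 1``; channel roles and
    flags go into vendor-extension keywords so a round trip through
    :func:`read_fcs` restores them exactly.
    """
    n_tot, n_par = table.values.shape
    kw_pairs: list[tuple[str, str]] = [
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$TIMESTEP", "1"),
        ("CYTODATRANSFORMED", "1" if table.transformed else "0"),
    ]
    for i, ch in enumerate(table.channels, start=1):
        col = table.values[:, i - 1]
        rng = float(col.max()) if n_tot else 1.0
        kw_pairs += [
            (f"$P{i}N", _escape(ch.name)),
            (f"$P{i}S", _escape(ch.marker)),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(np.ceil(rng)) + 1)),
            (f"{_ROLE_KEY[:6]}P{i}ROLE", ch.role),
            (
                f"{_FLAGS_KEY[:6]}P{i}FLAGS",
                ("1" if ch.use_for_lineage_clustering else "0")
                + ("1" if ch.use_for_embedding else "0"),
            ),
        ]

    data = table.values.astype("<f4").tobytes()
    # two-pass offset fixup: reserve fixed-width fields for data offsets
    begin_placeholder, end_placeholder = "%%BEGIN%%", "%%END%%"
    kw_pairs += [("$BEGINDATA", begin_placeholder), ("$ENDDATA", end_placeholder)]

    def render(begin: str, end: str) -> bytes:
        parts = [_DELIM]
        for k, v in kw_pairs:
            v = begin if v == begin_placeholder else end if v == end_placeholder else v
            parts.append(f"{k}{_DELIM}{v if v != '' else ' '}{_DELIM}")
        return "".join(parts).encode("utf-8")

    text_begin = 58
    text = render("0" * 12, "0" * 12)
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1 if data else 0
    text = render(str(data_begin).rjust(12, "0"), str(data_end).rjust(12, "0"))

    header = b"FCS3.1    "
    header += f"{text_begin:>8d}".encode()
    header += f"{text_end:>8d}".encode()
    # data offsets go in TEXT when they may exceed the 8-char header fields
    if data_end <= 99_999_999:
        header += f"{data_begin:>8d}".encode() + f"{data_end:>8d}".encode()
    else:
        header += b"       0" * 2
    header += b"       0" * 2  # no ANALYSIS segment

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


# ---------------------------------------------------------------------------
# CSV sidecars
# ---------------------------------------------------------------------------

def read_panel_csv(path) -> PanelDefinition:
    """Panel CSV columns: channel, marker, role, lineage, embedding."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"channel", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel CSV missing columns: {sorted(missing)}")

    def _flag(row, col):
        return str(row.get(col, "")).strip().lower() in ("1", "true", "yes")

    channels = [
        ChannelInfo(
            metal=row["channel"],
            marker=row.get("marker", ""),
            role=row["role"],
            use_for_lineage_clustering=_flag(row, "lineage"),
            use_for_embedding=_flag(row, "embedding"),
        )
        for _, row in df.iterrows()
    ]
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise ValidationError("panel CSV has duplicate channel names")
    return PanelDefinition(channels=channels)


def read_barcode_csv(path):
    """Barcode CSV: sample_id column plus one 0/1 column per barcode channel."""
    from .preprocess import BarcodeScheme  # local import to avoid a cycle

    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError("barcode CSV needs a 'sample_id' column")
    chan_cols = [c for c in df.columns if c != "sample_id"]
    codes = {
        row["sample_id"]: np.array([int(row[c]) for c in chan_cols], dtype=int)
        for _, row in df.iterrows()
    }
    return BarcodeScheme(barcode_channels=chan_cols, codes=codes)


def read_spillover_csv(path):
    """Spillover CSV: first column = source channel, remaining = receivers."""
    from .preprocess import SpilloverMatrix

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(
            "spillover CSV must be square with identical row/column channels; "
            f"rows={list(df.index)} cols={list(df.columns)}"
        )
    return SpilloverMatrix(channels=list(df.columns), S=df.to_numpy(dtype=float))


def read_metadata_csv(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, dtype={"sample_id": str}))


def read_sidecar_tables(panel_path, barcode_path, spillover_path, metadata_path):
    """Read and cross-validate the four sidecar CSVs.

    Checks: barcode channels are panel barcode channels; spillover channels
    are a subset of the panel; barcode codes match metadata samples.
    """
    panel = read_panel_csv(panel_path)
    scheme = read_barcode_csv(barcode_path)
    spill = read_spillover_csv(spillover_path)
    meta = read_metadata_csv(metadata_path)

    panel_names = set(panel.channel_names)
    bc_extra = [c for c in scheme.barcode_channels if c not in panel_names]
    if bc_extra:
        raise ValidationError(f"barcode channels not in panel: {bc_extra}")
    sp_extra = [c for c in spill.channels if c not in panel_names]
    if sp_extra:
        raise ValidationError(f"spillover channels not in panel: {sp_extra}")
    missing_codes = sorted(set(meta.sample_ids) - set(scheme.codes))
    if missing_codes:
        raise ValidationError(f"samples without barcode codes: {missing_codes}")
    return panel, scheme, spill, meta
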