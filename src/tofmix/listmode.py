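"""List-mode coincidence file format (text and flat binary), version 1.

A file starts with ASCII header lines ``# key = value``, one per
configuration item, terminated by ``# end_header``.  Records follow
either as tab-separated text rows or as raw little-endian binary in
:data:`EVENT_DTYPE` order.  The TOF sign convention is recorded in the
header: ``delta_t_ps = t_a - t_b``; a positive value displaces the
annihilation toward crystal b along the line of response.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .geometry import RingScanner

__all__ = [
    "EVENT_DTYPE",
    "COMP_NA",
    "COMP_FAST",
    "COMP_SLOW",
    "ListModeData",
    "write_listmode",
    "read_listmode",
]

EVENT_DTYPE = np.dtype(
    [
        ("ring_a", "<u2"),
        ("crystal_a", "<u2"),
        ("ring_b", "<u2"),
        ("crystal_b", "<u2"),
        ("delta_t_ps", "<f8"),
        ("kernel_id", "u1"),
        ("component_flag", "u1"),
    ]
)

#: component_flag values: no component (non-mixture model), fast, slow.
COMP_NA, COMP_FAST, COMP_SLOW = 0, 1, 2

_MAGIC = "tofmix-listmode v1"
_CONVENTION = (
    "delta_t_ps = t_a - t_b; positive delta_t displaces the annihilation "
    "toward crystal b by c*delta_t/2 along the LOR"
)


@dataclass
class ListModeData:
    """Coincidence events plus the provenance header they were written with."""

    events: np.ndarray
    header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=EVENT_DTYPE)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def scanner(self) -> RingScanner:
        h = self.header
        return RingScanner(
            n_crystals_per_ring=int(h["n_crystals_per_ring"]),
            n_rings=int(h["n_rings"]),
            ring_radius_mm=float(h["ring_radius_mm"]),
            crystal_pitch_transaxial_mm=float(h["crystal_pitch_transaxial_mm"]),
            crystal_pitch_axial_mm=float(h["crystal_pitch_axial_mm"]),
            crystal_depth_mm=float(h["crystal_depth_mm"]),
        )

    @staticmethod
    def scanner_header(scanner: RingScanner) -> dict:
        return {
            "n_crystals_per_ring": scanner.n_crystals_per_ring,
            "n_rings": scanner.n_rings,
            "ring_radius_mm": scanner.ring_radius_mm,
            "crystal_pitch_transaxial_mm": scanner.crystal_pitch_transaxial_mm,
            "crystal_pitch_axial_mm": scanner.crystal_pitch_axial_mm,
            "crystal_depth_mm": scanner.crystal_depth_mm,
        }


def _parse_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_listmode(path, data: ListModeData, fmt: str = "binary") -> None:
    """Write events to ``path``; ``fmt`` is ``"binary"`` or ``"text"``.

    Binary round-trips bit-exactly through :func:`read_listmode`.
    """
    if fmt not in ("binary", "text"):
        raise ValueError(f"unknown format {fmt!r}")
    header = dict(data.header)
    header["n_events"] = len(data.events)
    header["format"] = fmt
    header["convention"] = _CONVENTION
    lines = [f"# {_MAGIC}"]
    for key, value in header.items():
        lines.append(f"# {key} = {value}")
    lines.append("# columns = " + " ".join(EVENT_DTYPE.names))
    lines.append("# end_header")
    head = "\n".join(lines) + "\n"
    if fmt == "binary":
        with open(path, "wb") as fh:
            fh.write(head.encode("ascii"))
            fh.write(data.events.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(head)
            for ev in data.events:
                fh.write(
                    f"{ev['ring_a']}\t{ev['crystal_a']}\t{ev['ring_b']}\t"
                    f"{ev['crystal_b']}\t{float(ev['delta_t_ps'])!r}\t{ev['kernel_id']}\t"
                    f"{ev['component_flag']}\n"
                )


def read_listmode(path) -> ListModeData:
    with open(path, "rb") as fh:
        first = fh.readline().decode("ascii").strip()
        if first != f"# {_MAGIC}":
            raise ValueError(f"{path}: not a {_MAGIC} file")
        header: dict = {}
        while True:
            line = fh.readline().decode("ascii").strip()
            if not line.startswith("#"):
                raise ValueError(f"{path}: header not terminated")
            body = line[1:].strip()
            if body == "end_header":
                break
            key, _, value = body.partition("=")
            header[key.strip()] = _parse_value(value.strip())
        fmt = header.get("format", "binary")
        n = int(header.get("n_events", 0))
        if fmt == "binary":
            events = np.frombuffer(fh.read(n * EVENT_DTYPE.itemsize), dtype=EVENT_DTYPE)
        else:
            text = io.StringIO(fh.read().decode("ascii"))
            events = np.zeros(n, dtype=EVENT_DTYPE)
            for i in range(n):
                parts = text.readline().split()
                for name, value in zip(EVENT_DTYPE.names, parts):
                    events[i][name] = float(value)
    return ListModeData(events=events.copy(), header=header)
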