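"""Interactive review loop over a pipeline's QC PNGs.

A session is a front-end-agnostic state machine: an ordered (lexicographic,
hence identical for every reviewer) list of PNGs preloaded into memory,
a cursor, a viewed-set driving the "documents left to view" counter, a
montage mode for timed auto-advance, and a handle on the audit table.  Every
status change is persisted through :mod:`scanqc.qc_store` before the next
navigation event is accepted, so killing the session loses nothing.

Front ends (the CLI ships a minimal terminal loop) map arrow keys to
:func:`navigate`, ``y``/``m``/``n`` to :func:`set_status`, and drive montage
auto-advance by calling :func:`montage_tick` on the active mode's period.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from .bids_index import ScanIdentifier, parse_identifier
from .qc_store import QCRecord, QCTable, init_table, load_table, upsert, utc_now

__all__ = [
    "SessionState",
    "MONTAGE_PERIODS",
    "EmptySelectionError",
    "open_session",
    "navigate",
    "set_status",
    "set_montage",
    "montage_tick",
    "remaining",
]

#: montage auto-advance period in seconds per mode ("off" never fires)
MONTAGE_PERIODS = {"off": None, "slow": 1.0, "fast": 1.0 / 3.0}


class EmptySelectionError(FileNotFoundError):
    """No QC PNGs exist for the requested dataset/pipeline."""


@dataclass
class SessionState:
    items: list[tuple[ScanIdentifier, str]]     # (identifier, png path)
    images: list[bytes]                         # preloaded PNG bytes
    table: QCTable
    user: str
    cursor: int = 0
    viewed: set[int] = field(default_factory=set)
    montage: str = "off"

    def current(self) -> tuple[ScanIdentifier, str]:
        return self.items[self.cursor]

    def current_image(self) -> bytes:
        """PNG bytes of the item under the cursor, served unmodified."""
        return self.images[self.cursor]


def remaining(state: SessionState) -> int:
    """Documents left to view: total items minus distinct items viewed."""
    return len(state.items) - len(state.viewed)


def _table_path(archive_root: str, dataset: str, pipeline: str) -> str:
    return os.path.join(archive_root, dataset, pipeline, "qc_status.csv")


def open_session(archive_root: str, dataset: str, pipeline: str,
                 user: str) -> SessionState:
    """Open a review session on one dataset + pipeline.

    PNGs are pulled from the QC archive in lexicographic order and preloaded
    into memory before interaction begins.  The audit table is reloaded when
    it exists (saved statuses persist across sessions) and initialized to
    all-``yes`` otherwise.  Raises :class:`EmptySelectionError`, creating no
    table, when the selection holds no PNGs.
    """
    png_dir = os.path.join(archive_root, dataset, pipeline)
    pngs = []
    if os.path.isdir(png_dir):
        pngs = sorted(
            os.path.join(png_dir, f) for f in os.listdir(png_dir)
            if f.endswith(".png"))
    if not pngs:
        raise EmptySelectionError(
            f"no QC PNGs for dataset={dataset!r} pipeline={pipeline!r} "
            f"under {archive_root!r}")
    items = [
        (parse_identifier(p, dataset=dataset, pipeline=pipeline), p)
        for p in pngs
    ]
    images = []
    for _, p in items:
        with open(p, "rb") as fh:
            images.append(fh.read())
    path = _table_path(archive_root, dataset, pipeline)
    if os.path.exists(path):
        table = load_table(path)
    else:
        table = init_table([i for i, _ in items], user=user, path=path)
    state = SessionState(items=items, images=images, table=table, user=user)
    state.viewed.add(0)  # the first item is displayed on open
    return state


def navigate(state: SessionState, delta: int) -> SessionState:
    """Move the cursor by ``delta`` (±1), clamped at the ends.

    The newly displayed item counts as viewed; the remaining counter is
    therefore non-increasing over a session.
    """
    if not state.items:
        raise ValueError("session has no items")
    state.cursor = min(max(state.cursor + delta, 0), len(state.items) - 1)
    state.viewed.add(state.cursor)
    return state


def set_status(state: SessionState, status: str,
               note: str = "", timestamp: Optional[str] = None) -> SessionState:
    """Record a verdict for the item under the cursor and persist it.

    The montage, if running, pauses so the reviewer can finish writing the
    note.  Persistence happens before this call returns (upsert rewrites the
    CSV atomically), so state survives a kill.
    """
    if not state.items:
        raise ValueError("session has no items")
    ident, _ = state.current()
    record = QCRecord(identifier=ident, status=status, user=state.user,
                      timestamp=timestamp or utc_now(), note=note)
    upsert(state.table, record)
    if state.montage != "off":
        state.montage = "off"
    return state


def set_montage(state: SessionState, mode: str) -> SessionState:
    """Set timed auto-advance: off, slow (1 image/s) or fast (3 images/s)."""
    if mode not in MONTAGE_PERIODS:
        raise ValueError(f"montage mode must be one of {tuple(MONTAGE_PERIODS)}")
    if not state.items:
        raise ValueError("session has no items")
    state.montage = mode
    return state


def montage_tick(state: SessionState) -> SessionState:
    """One montage timer event: advance by one, stop at the last item.

    A no-op when montage is off.  Front ends call this every
    ``MONTAGE_PERIODS[state.montage]`` seconds.
    """
    if state.montage == "off":
        return state
    navigate(state, +1)
    if state.cursor == len(state.items) - 1:
        state.montage = "off"
    return state
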