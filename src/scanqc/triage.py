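"""Raw-data admission rules applied before any processing or QC.

Diffusion scans are admitted only when their gradient-table sidecars are
present and they carry enough volumes to be useful:

* a DWI without both its bval and bvec files is ignored
  (``MISSING_BVAL_BVEC``) — without the gradient table the diffusion
  weighting of each volume is unknown;
* a DWI with fewer than 6 volumes is ignored (``TOO_FEW_VOLUMES``) unless it
  is a reverse phase-encoding scan accompanying a more highly sampled DWI of
  the same subject and session, in which case it is kept for susceptibility
  distortion correction.

Structural (T1w) scans are always kept.  Triage never raises on data
content: the result is an exhaustive, disjoint partition of the inventory
into kept and ignored, with a machine-readable rule code and reason per
ignored scan — the substitute for the human step of asking data providers
for the missing files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bids_index import ScanIdentifier

__all__ = [
    "RawScan",
    "TriageReport",
    "SidecarFormatError",
    "SidecarConsistencyError",
    "triage_dwi",
    "read_sidecars",
    "write_triage_csv",
    "MIN_DWI_VOLUMES",
]

#: minimum volume count for a non-reverse-PE DWI to be admitted
MIN_DWI_VOLUMES = 6

RULE_MISSING_BVAL_BVEC = "MISSING_BVAL_BVEC"
RULE_TOO_FEW_VOLUMES = "TOO_FEW_VOLUMES"
RULE_NOT_A_SCAN = "NOT_A_SCAN"


class SidecarFormatError(ValueError):
    """A bval/bvec file whose shape is not the FSL dialect."""


class SidecarConsistencyError(ValueError):
    """bval and bvec disagree on the number of volumes."""


@dataclass(frozen=True)
class RawScan:
    """One scan in a raw-data inventory prior to triage."""

    identifier: ScanIdentifier
    modality: str  # "T1w" or "DWI"
    n_volumes: int = 1
    has_bval: bool = False
    has_bvec: bool = False
    pe_role: str = "unknown"  # "primary", "reverse_pe" or "unknown"
    companion: Optional[ScanIdentifier] = None

    def __post_init__(self) -> None:
        if self.modality not in ("T1w", "DWI"):
            raise ValueError(f"modality must be T1w or DWI, got {self.modality!r}")
        if self.pe_role not in ("primary", "reverse_pe", "unknown"):
            raise ValueError(f"bad pe_role: {self.pe_role!r}")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        if self.modality == "T1w" and self.n_volumes != 1:
            raise ValueError("T1w scans are single-volume")


@dataclass(frozen=True)
class TriageReport:
    """Partition of an inventory into kept and ignored scans."""

    kept: tuple[ScanIdentifier, ...]
    ignored: tuple[tuple[ScanIdentifier, str, str], ...]  # (identifier, rule_code, reason)

    @property
    def ignored_identifiers(self) -> tuple[ScanIdentifier, ...]:
        return tuple(i for i, _, _ in self.ignored)


def _passes_standalone(scan: RawScan) -> bool:
    """Both sidecar and volume-count rules, ignoring companion rescue."""
    return scan.has_bval and scan.has_bvec and scan.n_volumes >= MIN_DWI_VOLUMES


def triage_dwi(scans: Sequence[RawScan]) -> TriageReport:
    """Partition a raw inventory per the admission rules.

    Rules are applied in order: missing sidecars first, then the minimum
    volume count.  A reverse-PE scan is rescued from the volume-count rule
    only when a kept companion with >= 6 volumes exists in the same subject
    and session — companion dependence is evaluated live against this
    inventory, so removing the companion removes the rescue.
    """
    kept: list[ScanIdentifier] = []
    ignored: list[tuple[ScanIdentifier, str, str]] = []

    # scans that survive on their own merit, used to resolve companions
    standalone_kept = {
        s.identifier.key: s for s in scans
        if s.modality == "DWI" and _passes_standalone(s)
    }

    def _has_kept_companion(scan: RawScan) -> bool:
        for other in standalone_kept.values():
            if other.identifier.key == scan.identifier.key:
                continue
            if scan.companion is not None and other.identifier.key != scan.companion.key:
                continue
            same_site = (
                other.identifier.subject == scan.identifier.subject
                and other.identifier.session == scan.identifier.session
            )
            if same_site and other.n_volumes >= MIN_DWI_VOLUMES:
                return True
        return False

    for scan in scans:
        if scan.modality == "T1w":
            kept.append(scan.identifier)
            continue
        if not (scan.has_bval and scan.has_bvec):
            missing = [n for n, ok in (("bval", scan.has_bval), ("bvec", scan.has_bvec)) if not ok]
            ignored.append((
                scan.identifier,
                RULE_MISSING_BVAL_BVEC,
                f"DWI lacks {' and '.join(missing)} sidecar file(s)",
            ))
            continue
        if scan.n_volumes < MIN_DWI_VOLUMES:
            if scan.pe_role == "reverse_pe" and _has_kept_companion(scan):
                kept.append(scan.identifier)
            else:
                ignored.append((
                    scan.identifier,
                    RULE_TOO_FEW_VOLUMES,
                    f"DWI has {scan.n_volumes} volumes (< {MIN_DWI_VOLUMES}) "
                    "and is not a reverse-PE companion scan",
                ))
            continue
        kept.append(scan.identifier)

    return TriageReport(kept=tuple(kept), ignored=tuple(ignored))


def read_sidecars(bval_path: str, bvec_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect bval/bvec text sidecars.

    Returns ``(bvals, bvecs)`` with shapes ``(V,)`` and ``(V, 3)``.  The bvec
    file must hold exactly 3 whitespace-delimited rows of V columns; the bval
    file one row of V values.  Trailing whitespace and blank lines are
    tolerated.
    """
    with open(bval_path) as fh:
        bvals = np.array([float(x) for x in fh.read().split()])
    with open(bvec_path) as fh:
        rows = [line.split() for line in fh.read().splitlines() if line.strip()]
    if len(rows) != 3:
        raise SidecarFormatError(
            f"bvec file must have 3 rows, found {len(rows)}: {bvec_path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise SidecarFormatError(f"bvec rows have unequal lengths {sorted(lengths)}: {bvec_path}")
    bvecs = np.array(rows, dtype=float).T  # (V, 3)
    if len(bvals) != len(bvecs):
        raise SidecarConsistencyError(
            f"bval has {len(bvals)} entries but bvec has {len(bvecs)} columns")
    return bvals, bvecs


def write_triage_csv(report: TriageReport, path: str) -> None:
    """Persist a triage partition as CSV (identifier columns + rule + reason)."""
    cols = ["dataset", "subject", "session", "acquisition", "run", "pipeline",
            "item", "decision", "rule_code", "reason"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for ident in report.kept:
            w.writerow(list(ident.key[:1]) + list(ident.key[1:5]) + [ident.pipeline, ident.item, "kept", "", ""])
        for ident, rule, reason in report.ignored:
            w.writerow(list(ident.key[:1]) + list(ident.key[1:5]) + [ident.pipeline, ident.item, "ignored", rule, reason])
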