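"""BIDS-style naming, derivative indexing and automatic failure detection.

Pipeline outputs live in BIDS-like derivative trees
(``derivatives/<pipeline>/sub-XX[/ses-YY]/...``).  This module parses the
``sub-``/``ses-``/``acq-``/``run-`` entities out of file names, enumerates
every pipeline run under a derivatives root against a manifest of the files a
successful run must produce, and reports runs with missing outputs.  A run
that did not produce all of its intended outputs — its QC document included —
is automatically a QC failure.

Parsing is deliberately lenient: unrecognized entities are preserved in a
free-form suffix rather than rejected, so the tool remains usable on
near-BIDS data.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "ScanIdentifier",
    "OutputManifest",
    "FailureReport",
    "MalformedNameError",
    "parse_identifier",
    "format_identifier",
    "index_outputs",
    "detect_failures",
]

# Entities recognized in file names, in canonical BIDS order.
_KNOWN_ENTITIES = ("sub", "ses", "acq", "run", "dir")

_FORBIDDEN = re.compile(r"[,\n\r]")


class MalformedNameError(ValueError):
    """Raised for paths that carry no ``sub-`` entity."""


@dataclass(frozen=True, order=True)
class ScanIdentifier:
    """BIDS-tag tuple uniquely naming one pipeline output.

    The full tuple ``(dataset, subject, session, acquisition, run, pipeline,
    item)`` is the primary key of every QC table.  Optional entities are empty
    strings when absent.  No field may contain a comma or newline (the CSV
    audit format relies on that).
    """

    dataset: str = ""
    subject: str = ""
    session: str = ""
    acquisition: str = ""
    run: str = ""
    pipeline: str = ""
    item: str = ""

    def __post_init__(self) -> None:
        if not self.subject:
            raise ValueError("subject must be non-empty")
        for name, value in self.as_dict().items():
            if value and _FORBIDDEN.search(value):
                raise ValueError(f"identifier field {name!r} contains a comma or newline: {value!r}")

    def as_dict(self) -> dict[str, str]:
        return {
            "dataset": self.dataset,
            "subject": self.subject,
            "session": self.session,
            "acquisition": self.acquisition,
            "run": self.run,
            "pipeline": self.pipeline,
            "item": self.item,
        }

    @property
    def key(self) -> tuple[str, ...]:
        """The unique-row key used by QC tables."""
        return (self.dataset, self.subject, self.session, self.acquisition,
                self.run, self.pipeline, self.item)

    def with_item(self, item: str) -> "ScanIdentifier":
        return replace(self, item=item)


@dataclass(frozen=True)
class OutputManifest:
    """Files a successful run of one pipeline must produce.

    ``expected_items`` are glob patterns relative to the run directory, the
    pipeline's own QC document included when it emits one.
    """

    pipeline: str
    expected_items: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.expected_items:
            raise ValueError("expected_items must be non-empty")
        for pat in self.expected_items:
            if os.path.isabs(pat):
                raise ValueError(f"manifest pattern must be relative: {pat!r}")
        object.__setattr__(self, "expected_items", tuple(self.expected_items))


@dataclass(frozen=True)
class FailureReport:
    """One pipeline run that is an automatic QC failure.

    ``auto_status`` is always ``"no"``: a run missing any expected output
    fails QC without human review.
    """

    identifier: ScanIdentifier
    missing: tuple[str, ...]
    reason: str
    auto_status: str = "no"

    def __post_init__(self) -> None:
        if not self.missing:
            raise ValueError("a FailureReport needs at least one missing item")
        if self.auto_status != "no":
            raise ValueError("auto_status is fixed to 'no'")
        object.__setattr__(self, "missing", tuple(self.missing))


def parse_identifier(path: str, dataset: str = "", pipeline: str = "") -> ScanIdentifier:
    """Extract BIDS entities from a file path's basename.

    Recognizes ``sub-``, ``ses-``, ``acq-`` and ``run-``; every other
    ``key-value`` entity (and the trailing suffix) is ignored for identity
    purposes.  Raises :class:`MalformedNameError` when no ``sub-`` entity is
    present anywhere in the path.
    """
    base = os.path.basename(path)
    for ext in (".nii.gz", ".nii", ".png", ".pdf", ".bval", ".bvec", ".json"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    entities: dict[str, str] = {}
    for part in base.split("_"):
        key, sep, value = part.partition("-")
        if sep and value and key in _KNOWN_ENTITIES and key not in entities:
            entities[key] = f"{key}-{value}"
    if "sub" not in entities:
        # fall back to directory components (sub-XX/ses-YY/...)
        for comp in path.replace("\\", "/").split("/"):
            key, sep, value = comp.partition("-")
            if sep and value and key in ("sub", "ses") and key not in entities:
                entities[key] = comp
    if "sub" not in entities:
        raise MalformedNameError(f"no 'sub-' entity in path: {path!r}")
    return ScanIdentifier(
        dataset=dataset,
        subject=entities["sub"],
        session=entities.get("ses", ""),
        acquisition=entities.get("acq", ""),
        run=entities.get("run", ""),
        pipeline=pipeline,
    )


def format_identifier(ident: ScanIdentifier, suffix: str = "") -> str:
    """Inverse of :func:`parse_identifier`: a BIDS basename (no extension)."""
    parts = [p for p in (ident.subject, ident.session, ident.acquisition, ident.run) if p]
    if suffix:
        parts.append(suffix)
    return "_".join(parts)


def _run_directories(pipeline_root: str) -> list[str]:
    """Run directories beneath a pipeline root, lexicographically.

    A run directory is the deepest ``sub-*``/``ses-*`` level present:
    ``sub-XX`` alone when there are no sessions, else ``sub-XX/ses-YY``.
    """
    runs: list[str] = []
    if not os.path.isdir(pipeline_root):
        return runs
    for sub in sorted(os.listdir(pipeline_root)):
        sub_dir = os.path.join(pipeline_root, sub)
        if not (sub.startswith("sub-") and os.path.isdir(sub_dir)):
            continue
        sessions = sorted(
            s for s in os.listdir(sub_dir)
            if s.startswith("ses-") and os.path.isdir(os.path.join(sub_dir, s))
        )
        if sessions:
            runs.extend(os.path.join(sub, s) for s in sessions)
        else:
            runs.append(sub)
    return runs


def index_outputs(
    derivatives_root: str,
    manifest: OutputManifest,
    dataset: str = "",
) -> list[tuple[ScanIdentifier, list[str]]]:
    """Enumerate runs of one pipeline and the expected items each produced.

    Returns one ``(identifier, present_items)`` entry per run directory under
    ``derivatives_root/<pipeline>`` in deterministic lexicographic order.
    ``present_items`` is the subset of the manifest's patterns that match at
    least one file.  An empty or absent pipeline root yields an empty list.
    """
    import glob as _glob

    if not os.path.isdir(derivatives_root):
        raise IOError(f"derivatives root does not exist: {derivatives_root}")
    pipeline_root = os.path.join(derivatives_root, manifest.pipeline)
    out: list[tuple[ScanIdentifier, list[str]]] = []
    for rel in _run_directories(pipeline_root):
        run_dir = os.path.join(pipeline_root, rel)
        ident = parse_identifier(rel + "/x", dataset=dataset, pipeline=manifest.pipeline)
        present = [
            pat for pat in manifest.expected_items
            if _glob.glob(os.path.join(run_dir, pat), recursive=True)
        ]
        out.append((ident, present))
    return out


def detect_failures(
    indexed: list[tuple[ScanIdentifier, list[str]]],
    manifest: OutputManifest,
) -> list[FailureReport]:
    """Automatic QC failures: runs that did not produce all expected outputs.

    Each run with any missing manifest item yields one :class:`FailureReport`
    carrying ``auto_status="no"`` and a reason listing the absent patterns;
    complete runs yield nothing.
    """
    reports: list[FailureReport] = []
    for ident, present in indexed:
        missing = tuple(p for p in manifest.expected_items if p not in present)
        if missing:
            reports.append(FailureReport(
                identifier=ident,
                missing=missing,
                reason="missing expected outputs: " + "; ".join(missing),
            ))
    return reports
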