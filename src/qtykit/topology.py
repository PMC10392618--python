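"""Transmembrane topology: segment types, TSV/UniProt readers, and a
hydropathy-based predictor used as a fallback when no annotation exists.

Coordinates are 1-based inclusive throughout, matching the UniProt TRANSMEM
convention; conversion to 0-based slices happens only at array boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .hydropathy import hydropathy_profile

#: Helix count expected for a GLUT-like (MFS) transporter; warn-only check.
EXPECTED_GLUT_HELICES = 12


class TopologyError(ValueError):
    """Invalid transmembrane segment table."""


@dataclass(frozen=True)
class TMSegment:
    """One transmembrane helix span, 1-based inclusive."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise TopologyError(
                f"segment {self.label or ''}: need 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class TMTopology:
    """Ordered, non-overlapping transmembrane segments over one sequence.

    ``source`` records whether the segments came from an annotation table
    or from the hydropathy predictor; annotation always wins when both are
    available.
    """

    segments: tuple[TMSegment, ...] = ()
    source: str = "annotation"

    def __post_init__(self) -> None:
        if self.source not in ("annotation", "predicted"):
            raise TopologyError(f"unknown topology source {self.source!r}")
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise TopologyError(
                    f"segments overlap: ({prev.start},{prev.end}) and "
                    f"({cur.start},{cur.end})"
                )
        object.__setattr__(self, "segments", segs)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def n_tm_residues(self) -> int:
        return sum(len(s) for s in self.segments)

    def membership(self, length: int) -> np.ndarray:
        """Boolean mask of length *length*: True where the residue is TM."""
        if self.segments and self.segments[-1].end > length:
            raise TopologyError(
                f"topology extends to {self.segments[-1].end} but sequence "
                f"has only {length} residues"
            )
        mask = np.zeros(length, dtype=bool)
        for s in self.segments:
            mask[s.start - 1 : s.end] = True
        return mask

    def segment_at(self, position: int) -> TMSegment | None:
        for s in self.segments:
            if position in s:
                return s
        return None

    def check_glut_like(self) -> None:
        if len(self.segments) != EXPECTED_GLUT_HELICES:
            warnings.warn(
                f"topology has {len(self.segments)} segments; a GLUT-like "
                f"transporter is expected to have {EXPECTED_GLUT_HELICES}",
                stacklevel=2,
            )


def parse_tm_table(path: str | Path) -> dict[str, TMTopology]:
    """Read a TM table: tab-separated ``id<TAB>start<TAB>end[<TAB>label]``.

    Coordinates are 1-based inclusive. Rows for the same id are collected
    into one topology; overlaps or end < start raise :class:`TopologyError`.
    """
    per_id: dict[str, list[TMSegment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TopologyError(
                    f"{path}:{lineno}: expected id<TAB>start<TAB>end[<TAB>label]"
                )
            rec_id, start_s, end_s = parts[0].strip(), parts[1], parts[2]
            label = parts[3].strip() if len(parts) > 3 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise TopologyError(f"{path}:{lineno}: non-integer coordinate") from exc
            per_id.setdefault(rec_id, []).append(TMSegment(start, end, label))
    if not per_id:
        raise TopologyError(f"{path}: no segment rows found")
    return {rid: TMTopology(tuple(segs), source="annotation")
            for rid, segs in per_id.items()}


def write_tm_table(topologies: dict[str, TMTopology], path: str | Path) -> None:
    """Serialize topologies in the 4-column TSV format read by parse_tm_table."""
    with open(path, "w") as fh:
        for rid, topo in topologies.items():
            for seg in topo:
                fields = [rid, str(seg.start), str(seg.end)]
                if seg.label:
                    fields.append(seg.label)
                fh.write("\t".join(fields) + "\n")


_TRANSMEM_RE = re.compile(r"^FT\s+TRANSMEM\s+(\d+)\.\.(\d+)")


def parse_uniprot_transmem(path: str | Path, record_id: str = "") -> TMTopology:
    """Extract TRANSMEM ranges from UniProt flat-text ``FT`` lines.

    Accepts either a full UniProt text entry or a file containing just the
    ``FT   TRANSMEM   a..b`` lines. Helices are labelled TM1, TM2, ... in
    order of appearance.
    """
    segments: list[TMSegment] = []
    with open(path) as fh:
        for line in fh:
            m = _TRANSMEM_RE.match(line)
            if m:
                start, end = int(m.group(1)), int(m.group(2))
                segments.append(TMSegment(start, end, f"TM{len(segments) + 1}"))
    if not segments:
        raise TopologyError(f"{path}: no FT TRANSMEM lines found")
    return TMTopology(tuple(segments), source="annotation")


def predict_tm_segments(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    merge_gap: int = 3,
) -> TMTopology:
    """Predict TM helices from Kyte-Doolittle hydropathy.

    A residue is marked TM when any length-*window* window containing it has
    mean hydropathy above *threshold* (equivalently, above-threshold window
    centres expanded by half a window each side). Marked runs separated by
    at most *merge_gap* residues are merged, then runs shorter than
    *min_len* are discarded. The result carries ``source="predicted"``.
    """
    profile = hydropathy_profile(seq, window=window)
    length = len(seq)
    mask = np.zeros(length, dtype=bool)
    for i in np.flatnonzero(profile > threshold):
        # profile[i] covers residues i+1 .. i+window (1-based)
        mask[i : i + window] = True

    runs: list[list[int]] = []  # [start, end] 0-based inclusive
    for pos in map(int, np.flatnonzero(mask)):
        if runs and pos - runs[-1][1] - 1 <= merge_gap:
            runs[-1][1] = pos
        else:
            runs.append([pos, pos])
    segments = [
        TMSegment(a + 1, b + 1)
        for a, b in runs
        if (b - a + 1) >= min_len
    ]
    segments = [
        TMSegment(s.start, s.end, f"TM{i}") for i, s in enumerate(segments, 1)
    ]
    return TMTopology(tuple(segments), source="predicted")


def topology_for(
    record_length: int,
    annotated: TMTopology | None,
    sequence: str | None = None,
    **predict_kwargs,
) -> TMTopology:
    """Resolve the topology to use: annotation wins; prediction is fallback."""
    if annotated is not None:
        annotated.membership(record_length)  # range check
        return annotated
    if sequence is None:
        raise TopologyError("no annotation supplied and no sequence to predict from")
    return predict_tm_segments(sequence, **predict_kwargs)
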