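"""Hypnogram container and I/O for epoch-scored sleep-stage records.

Three on-disk dialects are supported:

* ``epoch_csv`` — header ``epoch,stage``, one row per epoch, epoch index
  strictly increasing from 0;
* ``nsrr_xml`` — the minimal subset of the NSRR scored-event annotation
  XML carrying stage events (event type "Stages", stage token, start and
  duration in seconds);
* ``stage_string`` — whitespace-delimited tokens, or a bare concatenation
  of canonical codes.

Stage labels are normalized to the canonical alphabet {W, N1, N2, N3, R};
legacy R&K stage 4 is merged into N3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml
from lxml import etree

CANONICAL_STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
NREM_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3"})

Format = Literal["epoch_csv", "nsrr_xml", "stage_string"]
FORMATS: tuple[str, ...] = ("epoch_csv", "nsrr_xml", "stage_string")

#: NSRR numeric scoring codes plus common textual aliases. R&K stage 4 is
#: mapped to N3 (modern AASM scoring merges the two slow-wave stages).
_DEFAULT_MAPPING: dict[str, str] = {
    "0": "W",
    "1": "N1",
    "2": "N2",
    "3": "N3",
    "4": "N3",
    "5": "R",
    "W": "W",
    "N1": "N1",
    "N2": "N2",
    "N3": "N3",
    "N4": "N3",
    "R": "R",
    "Wake": "W",
    "REM": "R",
    "Stage1": "N1",
    "Stage2": "N2",
    "Stage3": "N3",
    "Stage4": "N3",
}

#: Tokens conventionally used for unscored / movement epochs.
_DEFAULT_UNSCORED: frozenset[str] = frozenset({"9", "?", "U", "M", "Unscored", "Movement"})


class HypnogramError(ValueError):
    """Raised when a record cannot be parsed or fails its invariants."""


@dataclass(frozen=True)
class StageLabelMap:
    """Mapping from source stage tokens to canonical codes.

    Parameters
    ----------
    mapping
        Token -> canonical code. Must cover every token encountered in a
        record; an unmapped token aborts the read with its position.
    unscored_tokens
        Tokens treated as unscored/movement epochs, resolved per
        ``unscored_policy``.
    unscored_policy
        ``"carry_forward"`` (default) makes an unscored epoch inherit the
        previous epoch's stage; ``"reject"`` aborts on the first unscored
        token. Regardless of policy, a record whose first epoch is
        unscored, or with more than ``max_unscored_fraction`` unscored
        epochs, is rejected.
    """

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_MAPPING))
    unscored_tokens: frozenset[str] = _DEFAULT_UNSCORED
    unscored_policy: Literal["carry_forward", "reject"] = "carry_forward"
    max_unscored_fraction: float = 0.10

    def __post_init__(self) -> None:
        for token, code in self.mapping.items():
            if code not in CANONICAL_STAGES:
                raise HypnogramError(
                    f"label map sends {token!r} to non-canonical code {code!r}"
                )
        if self.unscored_policy not in ("carry_forward", "reject"):
            raise HypnogramError(f"unknown unscored_policy {self.unscored_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StageLabelMap":
        """Load a label map from a small YAML config.

        Recognized keys: ``mapping`` (token -> code), ``unscored_tokens``
        (list), ``unscored_policy``, ``max_unscored_fraction``. Omitted
        keys fall back to the shipped defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "mapping" in raw:
            kwargs["mapping"] = {str(k): str(v) for k, v in raw["mapping"].items()}
        if "unscored_tokens" in raw:
            kwargs["unscored_tokens"] = frozenset(str(t) for t in raw["unscored_tokens"])
        if "unscored_policy" in raw:
            kwargs["unscored_policy"] = raw["unscored_policy"]
        if "max_unscored_fraction" in raw:
            kwargs["max_unscored_fraction"] = float(raw["max_unscored_fraction"])
        return cls(**kwargs)


def default_label_map() -> StageLabelMap:
    """The shipped default: NSRR numeric codes, carry-forward unscored."""
    return StageLabelMap()


@dataclass(frozen=True)
class Hypnogram:
    """An epoch-scored night: one canonical stage code per fixed epoch.

    Epoch indices are 0-based; an episode occupying epochs [s, s+L) is
    half-open.
    """

    record_id: str
    stages: tuple[str, ...]
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise HypnogramError(f"{self.record_id}: empty record")
        if self.epoch_seconds <= 0:
            raise HypnogramError(f"{self.record_id}: epoch_seconds must be > 0")
        bad = next(
            ((i, s) for i, s in enumerate(self.stages) if s not in CANONICAL_STAGES),
            None,
        )
        if bad is not None:
            raise HypnogramError(
                f"{self.record_id}: non-canonical stage {bad[1]!r} at epoch {bad[0]}"
            )
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_seconds(self) -> float:
        return self.n_epochs * self.epoch_seconds


def _apply_label_map(
    tokens: Sequence[str], label_map: StageLabelMap, record_id: str
) -> list[str]:
    """Map raw tokens to canonical codes, resolving unscored epochs."""
    n = len(tokens)
    unscored = [t in label_map.unscored_tokens for t in tokens]
    n_unscored = sum(unscored)
    if n_unscored:
        if label_map.unscored_policy == "reject":
            pos = unscored.index(True)
            raise HypnogramError(
                f"{record_id}: unscored token {tokens[pos]!r} at epoch {pos} "
                "(policy=reject)"
            )
        if unscored[0]:
            raise HypnogramError(f"{record_id}: first epoch is unscored")
        if n_unscored / n > label_map.max_unscored_fraction:
            raise HypnogramError(
                f"{record_id}: {n_unscored}/{n} unscored epochs exceeds "
                f"{label_map.max_unscored_fraction:.0%}"
            )
    out: list[str] = []
    for i, tok in enumerate(tokens):
        if unscored[i]:
            out.append(out[-1])  # carry forward previous epoch's stage
            continue
        code = label_map.mapping.get(tok)
        if code is None:
            raise HypnogramError(
                f"{record_id}: unmapped stage token {tok!r} at epoch {i}"
            )
        out.append(code)
    return out


# ---------------------------------------------------------------------------
# epoch_csv
# ---------------------------------------------------------------------------

def _read_epoch_csv(path: Path, label_map: StageLabelMap, epoch_seconds: float,
                    record_id: str) -> Hypnogram:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["epoch", "stage"]:
        raise HypnogramError(f"{record_id}: expected header 'epoch,stage', got {list(df.columns)}")
    if len(df) == 0:
        raise HypnogramError(f"{record_id}: empty record")
    epochs = df["epoch"].astype(int).to_numpy()
    if not (epochs == range(len(df))).all():
        raise HypnogramError(f"{record_id}: epoch column must increase 0,1,2,...")
    stages = _apply_label_map(df["stage"].tolist(), label_map, record_id)
    return Hypnogram(record_id, tuple(stages), epoch_seconds)


def _write_epoch_csv(h: Hypnogram, path: Path) -> None:
    pd.DataFrame({"epoch": range(h.n_epochs), "stage": h.stages}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# nsrr_xml
# ---------------------------------------------------------------------------

def _read_nsrr_xml(path: Path, label_map: StageLabelMap, epoch_seconds: float,
                   record_id: str) -> Hypnogram:
    tree = etree.parse(str(path))
    events = []
    for ev in tree.iter("ScoredEvent"):
        ev_type = ev.findtext("EventType") or ""
        if "Stages" not in ev_type:
            continue
        concept = ev.findtext("EventConcept") or ""
        token = concept.split("|")[-1].strip()
        start = float(ev.findtext("Start"))
        dur = float(ev.findtext("Duration"))
        events.append((start, dur, token))
    if not events:
        raise HypnogramError(f"{record_id}: no stage events found")
    events.sort(key=lambda e: e[0])
    tokens: list[str] = []
    expected_start = 0.0
    for start, dur, token in events:
        if abs(start - expected_start) > 1e-6:
            kind = "overlapping" if start < expected_start else "gapped"
            raise HypnogramError(
                f"{record_id}: {kind} stage events at t={start} s (expected {expected_start} s)"
            )
        n_rep = dur / epoch_seconds
        if abs(n_rep - round(n_rep)) > 1e-9 or round(n_rep) < 1:
            raise HypnogramError(
                f"{record_id}: event duration {dur} s at t={start} s is not a "
                f"positive multiple of epoch_seconds={epoch_seconds}"
            )
        tokens.extend([token] * int(round(n_rep)))
        expected_start = start + dur
    stages = _apply_label_map(tokens, label_map, record_id)
    return Hypnogram(record_id, tuple(stages), epoch_seconds)


def _write_nsrr_xml(h: Hypnogram, path: Path) -> None:
    # one event per maximal same-stage run, canonical codes as stage tokens
    root = etree.Element("PSGAnnotation")
    scored = etree.SubElement(root, "ScoredEvents")
    i = 0
    while i < h.n_epochs:
        j = i
        while j < h.n_epochs and h.stages[j] == h.stages[i]:
            j += 1
        ev = etree.SubElement(scored, "ScoredEvent")
        etree.SubElement(ev, "EventType").text = "Stages|Stages"
        etree.SubElement(ev, "EventConcept").text = h.stages[i]
        etree.SubElement(ev, "Start").text = f"{i * h.epoch_seconds:g}"
        etree.SubElement(ev, "Duration").text = f"{(j - i) * h.epoch_seconds:g}"
        i = j
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# stage_string
# ---------------------------------------------------------------------------

_CANON_TOKEN_RE = re.compile(r"N1|N2|N3|W|R")


def _tokenize_stage_string(text: str) -> list[str]:
    text = text.strip()
    if not text:
        return []
    if any(c.isspace() for c in text):
        return text.split()
    # bare concatenation of canonical codes, e.g. "WWN1N2N2R"
    tokens = _CANON_TOKEN_RE.findall(text)
    if "".join(tokens) != text:
        raise HypnogramError(f"stage string contains non-canonical characters: {text[:40]!r}")
    return tokens


def _read_stage_string(path: Path, label_map: StageLabelMap, epoch_seconds: float,
                       record_id: str) -> Hypnogram:
    tokens = _tokenize_stage_string(Path(path).read_text())
    if not tokens:
        raise HypnogramError(f"{record_id}: empty record")
    stages = _apply_label_map(tokens, label_map, record_id)
    return Hypnogram(record_id, tuple(stages), epoch_seconds)


def _write_stage_string(h: Hypnogram, path: Path) -> None:
    Path(path).write_text(" ".join(h.stages) + "\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_READERS = {
    "epoch_csv": _read_epoch_csv,
    "nsrr_xml": _read_nsrr_xml,
    "stage_string": _read_stage_string,
}
_WRITERS = {
    "epoch_csv": _write_epoch_csv,
    "nsrr_xml": _write_nsrr_xml,
    "stage_string": _write_stage_string,
}

_EXTENSIONS = {"epoch_csv": ".csv", "nsrr_xml": ".xml", "stage_string": ".txt"}


def format_from_path(path: str | Path) -> str:
    """Guess the dialect from a file extension (.csv/.xml/.txt)."""
    ext = Path(path).suffix.lower()
    for fmt, e in _EXTENSIONS.items():
        if ext == e:
            return fmt
    raise HypnogramError(f"cannot infer hypnogram format from extension {ext!r}")


def read_hypnogram(
    path: str | Path,
    format: str | None = None,
    label_map: StageLabelMap | None = None,
    epoch_seconds: float = 30.0,
    record_id: str | None = None,
) -> Hypnogram:
    """Read one hypnogram.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``epoch_csv``, ``nsrr_xml``, ``stage_string``; inferred
        from the extension when omitted.
    label_map
        Token normalization; defaults to the shipped NSRR map.
    epoch_seconds
        Scoring epoch length (default 30 s). NSRR stage-event durations
        must be positive multiples of this.
    record_id
        Defaults to the file stem.
    """
    path = Path(path)
    fmt = format or format_from_path(path)
    if fmt not in _READERS:
        raise HypnogramError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    rid = record_id if record_id is not None else path.stem
    return _READERS[fmt](path, label_map or default_label_map(), float(epoch_seconds), rid)


def write_hypnogram(h: Hypnogram, path: str | Path, format: str | None = None) -> None:
    """Write a hypnogram; round-trips exactly through :func:`read_hypnogram`."""
    path = Path(path)
    fmt = format or format_from_path(path)
    if fmt not in _WRITERS:
        raise HypnogramError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    _WRITERS[fmt](h, path)


def from_stages(stages: Iterable[str], record_id: str = "record",
                epoch_seconds: float = 30.0) -> Hypnogram:
    """Build a hypnogram directly from canonical stage codes."""
    return Hypnogram(record_id, tuple(stages), epoch_seconds)
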