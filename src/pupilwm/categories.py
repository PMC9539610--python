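"""Derivation of color-category boundaries and prototypes from hue labeling.

In a hue-categorization experiment every participant assigns each of the
360 integer hues of the HSV color circle to one of seven basic color
labels.  Aggregating these responses gives, for every hue, a modal label;
hues where the modal label flips between neighbours are category
boundaries (maximally ambiguous hues), and the circular midpoint between
two consecutive boundaries is the category prototype.

The boundary is placed at the midpoint h + 0.5 between the two hues whose
modal labels differ.  With noisy data the modal sequence can flicker at a
boundary; a persistence filter only accepts a label change if the new
label stays modal for at least ``persistence`` consecutive hues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COLOR_LABELS_7",
    "CategorySolution",
    "response_frequencies",
    "modal_labels",
    "find_boundaries",
    "find_prototypes",
    "derive_categories",
    "rater_agreement",
]

# the seven basic color labels, in hue order starting from 0 degrees (red)
COLOR_LABELS_7 = ["red", "orange", "yellow", "green", "blue", "purple", "pink"]


def circular_midpoint(a: float, b: float) -> float:
    """Midpoint of the arc from ``a`` forward (increasing hue) to ``b``."""
    return (a + ((b - a) % 360.0) / 2.0) % 360.0


@dataclass
class CategorySolution:
    """Category boundaries, prototypes and labels on the 360-degree circle.

    ``boundaries`` are sorted ascending; category ``i`` covers the arc from
    ``boundaries[i]`` forward to ``boundaries[(i + 1) % n]`` and has
    prototype ``prototypes[i]`` (the circular midpoint of that arc) and
    name ``labels[i]``.
    """

    boundaries: np.ndarray
    prototypes: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float) % 360.0
        self.prototypes = np.asarray(self.prototypes, dtype=float) % 360.0
        if len(self.boundaries) != len(self.prototypes):
            raise ValueError("boundaries and prototypes must have equal length")
        if not self.labels:
            self.labels = [f"c{i}" for i in range(len(self.boundaries))]
        if len(self.labels) != len(self.boundaries):
            raise ValueError("labels length must match boundaries")
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be sorted ascending and distinct")

    @property
    def n_categories(self) -> int:
        return len(self.boundaries)

    def category_of(self, hue) -> np.ndarray:
        """Index of the category whose arc contains each hue."""
        h = np.asarray(hue, dtype=float) % 360.0
        idx = (np.searchsorted(self.boundaries, h, side="right") - 1) % self.n_categories
        if idx.ndim == 0:
            return int(idx)
        return idx

    def label_of(self, hue):
        idx = self.category_of(hue)
        if np.ndim(idx) == 0:
            return self.labels[idx]
        return [self.labels[i] for i in idx]

    def flanking_categories(self, boundary_index: int) -> tuple:
        """The two category indices meeting at a boundary (below, above)."""
        n = self.n_categories
        return ((boundary_index - 1) % n, boundary_index % n)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"labels": list(self.labels),
             "boundaries": [float(b) for b in self.boundaries],
             "prototypes": [float(p) for p in self.prototypes]}, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CategorySolution":
        if isinstance(source, (str,)) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                obj = json.load(fh)
        return cls(boundaries=np.array(obj["boundaries"]),
                   prototypes=np.array(obj["prototypes"]),
                   labels=list(obj["labels"]))


def circular_max_error(estimated, truth) -> float:
    """Largest circular distance from any true value to its nearest estimate.

    Useful for judging recovery of boundary/prototype sets, which are only
    defined up to circular ordering.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    d = np.abs((est[None, :] - tru[:, None] + 180.0) % 360.0 - 180.0)
    return float(d.min(axis=1).max())


def response_frequencies(records: pd.DataFrame,
                         labels=None) -> pd.DataFrame:
    """Tabulate label counts per hue from categorization records.

    ``records`` needs columns hue (integer 0-359) and label.  Returns a
    360 x n_labels count table (hue index, label columns).  Unknown labels
    raise a ValueError naming the offending value.
    """
    if len(records) == 0:
        raise ValueError("no categorization records")
    hues = records["hue"].to_numpy()
    if np.any((hues < 0) | (hues > 359) | (hues != np.floor(hues))):
        bad = hues[(hues < 0) | (hues > 359) | (hues != np.floor(hues))][0]
        raise ValueError(f"hue values must be integers in [0, 359]; got {bad}")
    if labels is None:
        labels = sorted(records["label"].unique())
    else:
        unknown = set(records["label"].unique()) - set(labels)
        if unknown:
            raise ValueError(f"unknown label(s): {sorted(unknown)}")
    table = pd.crosstab(records["hue"], records["label"])
    table = table.reindex(index=range(360), columns=list(labels), fill_value=0)
    table.index.name = "hue"
    return table


def modal_labels(table: pd.DataFrame) -> np.ndarray:
    """Most frequent label per hue; ties keep the previous hue's modal label.

    The tie rule is applied circularly: resolution starts from a hue whose
    winner is unique and sweeps forward around the circle, so a tied hue
    inherits the modal label of its predecessor (continuity).
    """
    counts = table.to_numpy()
    if np.any(counts.sum(axis=1) == 0):
        bad = int(np.argmin(counts.sum(axis=1) > 0))
        raise ValueError(f"hue {bad} has no responses")
    labels = np.asarray(table.columns)
    max_count = counts.max(axis=1)
    tied = (counts == max_count[:, None]).sum(axis=1) > 1
    winner = labels[np.argmax(counts, axis=1)].astype(object)
    if not tied.any():
        return winner
    anchors = np.flatnonzero(~tied)
    if len(anchors) == 0:
        raise ValueError("every hue is tied; modal sequence undefined")
    start = anchors[0]
    out = winner.copy()
    for step in range(1, 360):
        h = (start + step) % 360
        if tied[h]:
            prev = out[(h - 1) % 360]
            if counts[h, np.flatnonzero(labels == prev)[0]] == max_count[h]:
                out[h] = prev
            # a tie not involving the previous label keeps the argmax winner
    return out


def find_boundaries(modal, persistence: int = 3) -> np.ndarray:
    """Boundary hues of a circular modal-label sequence.

    A boundary sits at ``h + 0.5`` whenever the modal label differs between
    hues ``h`` and ``h + 1`` (mod 360) *and* the new label persists for at
    least ``persistence`` consecutive hues; shorter flickers are ignored.
    Returns a sorted array; a constant sequence yields an empty one.
    """
    modal = np.asarray(modal, dtype=object)
    n = modal.size
    if n != 360:
        raise ValueError("modal sequence must cover hues 0..359")
    if len(set(modal.tolist())) == 1:
        return np.array([], dtype=float)

    def run_length(i):
        lab, k = modal[i % n], 0
        while k < n and modal[(i + k) % n] == lab:
            k += 1
        return k

    # anchor: start of a run of length >= persistence
    anchor = None
    for i in range(n):
        if modal[i] != modal[(i - 1) % n] and run_length(i) >= persistence:
            anchor = i
            break
    if anchor is None:
        raise ValueError(
            f"no label persists for {persistence} consecutive hues")
    boundaries = []
    current = modal[anchor]
    for step in range(1, n + 1):
        h = (anchor + step) % n
        lab = modal[h]
        if lab != current and run_length(h) >= persistence:
            boundaries.append(((h - 1) + 0.5) % 360.0)
            current = lab
    return np.sort(np.array(boundaries, dtype=float))


def find_prototypes(boundaries) -> np.ndarray:
    """Circular midpoints between consecutive boundaries.

    ``prototypes[i]`` is the midpoint of the arc from ``boundaries[i]``
    forward to the next boundary (wrapping past 360); it is the prototype
    of the category enclosed by that pair.
    """
    b = np.sort(np.asarray(boundaries, dtype=float) % 360.0)
    if b.size < 2:
        raise ValueError("need at least 2 boundaries")
    nxt = np.roll(b, -1)
    return np.array([circular_midpoint(lo, hi) for lo, hi in zip(b, nxt)])


def derive_categories(records: pd.DataFrame, labels=None,
                      persistence: int = 3) -> CategorySolution:
    """Full pipeline: records -> frequency table -> boundaries -> prototypes."""
    table = response_frequencies(records, labels=labels)
    modal = modal_labels(table)
    boundaries = find_boundaries(modal, persistence=persistence)
    if boundaries.size < 2:
        raise ValueError("fewer than 2 boundaries recovered")
    prototypes = find_prototypes(boundaries)
    # category i starts just above boundaries[i]; name it by its modal label
    cat_labels = [modal[int(np.ceil(b)) % 360] for b in boundaries]
    return CategorySolution(boundaries=boundaries, prototypes=prototypes,
                            labels=cat_labels)


def rater_agreement(records: pd.DataFrame, threshold: float = 0.5,
                    labels=None) -> pd.DataFrame:
    """Leave-one-out agreement of each participant with the group modal label.

    For every participant the modal label per hue is recomputed from all
    *other* participants; the agreement score is the fraction of the
    participant's own responses matching that label.  Participants scoring
    below ``threshold`` are flagged.  This is a quantitative surrogate for
    excluding raters whose responses deviate strongly from the average.
    """
    participants = records["participant"].unique()
    if len(participants) < 2:
        raise ValueError("agreement needs at least 2 participants")
    rows = []
    for pp in participants:
        own = records[records["participant"] == pp]
        others = records[records["participant"] != pp]
        modal = modal_labels(response_frequencies(others, labels=labels))
        match = own["label"].to_numpy() == modal[own["hue"].to_numpy()]
        score = float(np.mean(match))
        rows.append({"participant": pp, "agreement": score,
                     "flagged": score < threshold})
    return pd.DataFrame(rows)
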