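"""Space-time typing of SOs via co-detection clustering.

Each detected SO seeds a binary co-detection vector over the head
electrodes: electrode c is set when an SO trough on c falls within the
co-detection delay (400 ms by default, symmetric) of the seeding event's
trough. The events × electrodes binary matrix is clustered with k-means
under Hamming distance (k = 3, majority-vote binary centroids — the
k-modes update, which is what Hamming k-means reduces to on binary
data), and the three clusters are labelled Global, Frontal or Local from
their centroid topography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detection import SOEvent

logger = logging.getLogger(__name__)

SO_TYPES = ("Global", "Local", "Frontal")


@dataclass
class CoDetectionMatrix:
    """Binary events × electrodes co-detection matrix."""

    values: np.ndarray
    event_index: list[SOEvent] | list[int]
    electrode_names: list[str]
    delay: float = 0.4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("co-detection entries must be 0/1")
        self.values = self.values.astype(np.uint8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.electrode_names):
            raise ValueError("matrix must be events × electrodes")
        if len(self.event_index) != self.values.shape[0]:
            raise ValueError("one event reference per row required")
        if self.values.size and not self.values.any(axis=1).all():
            raise ValueError("every row must contain its own seeding electrode")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


@dataclass
class SOClusterModel:
    """k = 3 Hamming clustering of co-detection vectors, with type labels."""

    centroids: np.ndarray            # 3 × electrodes, binary
    assignment: np.ndarray           # cluster id per event
    inertia: float                   # total Hamming cost
    electrode_names: list[str]
    type_map: dict[int, str] = field(default_factory=dict)

    def types(self) -> np.ndarray:
        """Per-event SO type labels (requires :func:`label_clusters`)."""
        if not self.type_map:
            raise ValueError("clusters are not labelled yet")
        return np.array([self.type_map[a] for a in self.assignment])

    def is_global(self) -> np.ndarray:
        return self.types() == "Global"


def build_codetection(events: list[SOEvent], electrodes: list[str],
                      delay: float = 0.4) -> CoDetectionMatrix:
    """Binary co-detection matrix for one subject/stage pool of events.

    Row r, column c is 1 iff some event on electrode c has a trough
    within ``delay`` seconds (symmetric window) of event r's trough; the
    seeding electrode itself is always set.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    col = {e: i for i, e in enumerate(electrodes)}
    missing = {ev.channel for ev in events} - set(electrodes)
    if missing:
        raise ValueError(f"events on electrodes outside the head set: {sorted(missing)}")
    values = np.zeros((len(events), len(electrodes)), dtype=np.uint8)
    troughs = np.array([ev.t_trough for ev in events])
    cols = np.array([col[ev.channel] for ev in events], dtype=int) if events else np.array([], int)
    for r, ev in enumerate(events):
        near = np.abs(troughs - ev.t_trough) <= delay
        values[r, cols[near]] = 1
        values[r, col[ev.channel]] = 1
    return CoDetectionMatrix(values=values, event_index=list(events),
                             electrode_names=list(electrodes), delay=delay)


def _hamming_cost(X: np.ndarray, centroids: np.ndarray,
                  assignment: np.ndarray) -> int:
    return int((X != centroids[assignment]).sum())


def _lloyd_hamming(X: np.ndarray, init: np.ndarray, max_iter: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """One Lloyd run with Hamming distance and majority-vote updates."""
    k = init.shape[0]
    centroids = init.copy()
    assignment = np.zeros(X.shape[0], dtype=int)
    prev_cost = None
    for _ in range(max_iter):
        # assignment step: Hamming distance to each binary centroid
        dists = (X[:, None, :] != centroids[None, :, :]).sum(axis=2)
        assignment = dists.argmin(axis=1)
        cost = _hamming_cost(X, centroids, assignment)
        assert prev_cost is None or cost <= prev_cost, "Lloyd cost increased"
        if cost == prev_cost:
            break
        prev_cost = cost
        # update step: per-electrode majority vote, ties toward 1
        for j in range(k):
            members = X[assignment == j]
            if len(members) == 0:
                # re-seed an empty cluster at the row farthest from its centroid
                far = dists[np.arange(len(X)), assignment].argmax()
                centroids[j] = X[far]
            else:
                centroids[j] = (members.mean(axis=0) >= 0.5).astype(np.uint8)
    cost = _hamming_cost(X, centroids, assignment)
    return centroids, assignment, cost


def kmeans_hamming(m: CoDetectionMatrix, k: int = 3, replicates: int = 200,
                   max_iter: int = 10_000, seed: int | None = 0) -> SOClusterModel:
    """Best-of-replicates Hamming k-means on the co-detection matrix.

    Runs ``replicates`` Lloyd iterations from random distinct-row
    initialisations and keeps the solution with the lowest total Hamming
    cost. Deterministic for a fixed seed.
    """
    X = m.values.astype(np.uint8)
    uniq = np.unique(X, axis=0)
    if uniq.shape[0] < k:
        raise ValueError(
            f"need at least {k} distinct co-detection rows, found {uniq.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, int] | None = None
    for _ in range(replicates):
        init_rows = rng.choice(uniq.shape[0], size=k, replace=False)
        result = _lloyd_hamming(X, uniq[init_rows], max_iter, rng)
        if best is None or result[2] < best[2]:
            best = result
        if best[2] == 0:
            break
    centroids, assignment, cost = best
    return SOClusterModel(centroids=centroids, assignment=assignment,
                          inertia=float(cost),
                          electrode_names=list(m.electrode_names))


def label_clusters(model: SOClusterModel, frontal: list[str],
                   posterior: list[str]) -> SOClusterModel:
    """Assign Global / Frontal / Local labels from centroid topography.

    Global is the centroid with the greatest mean co-detection over all
    electrodes; of the remaining two, Frontal is the one with the larger
    frontal-minus-posterior mean difference; the last is Local. Ties on
    the Global criterion are broken by cluster size (larger wins).
    """
    names = model.electrode_names
    f_idx = [names.index(e) for e in frontal if e in names]
    p_idx = [names.index(e) for e in posterior if e in names]
    if not f_idx or not p_idx:
        raise ValueError("frontal/posterior partition does not match electrodes")
    coverage = model.centroids.mean(axis=1)
    sizes = np.bincount(model.assignment, minlength=model.centroids.shape[0])
    order = sorted(range(len(coverage)),
                   key=lambda j: (coverage[j], sizes[j]), reverse=True)
    if coverage[order[0]] == coverage[order[1]]:
        logger.info("coverage tie for Global broken by cluster size")
    global_id = order[0]
    rest = order[1:]
    frontality = [
        model.centroids[j, f_idx].mean() - model.centroids[j, p_idx].mean()
        for j in rest
    ]
    frontal_id = rest[int(np.argmax(frontality))]
    local_id = next(j for j in rest if j != frontal_id)
    model.type_map = {global_id: "Global", frontal_id: "Frontal",
                      local_id: "Local"}
    return model
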