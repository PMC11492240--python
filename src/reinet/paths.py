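"""Shortest-path analysis of residue networks.

All-pairs shortest paths (Dijkstra, via scipy's sparse-graph routines)
give an N×N matrix of path costs; the per-residue average over a
residue's column is its *average shortest-path length* — the lower, the
better connected the residue, and a perturbation there is expected to be
the more disruptive. Profiles are mean-normalized (profile mean = 1) so
networks whose costs carry different units (Å, mol/kcal, inverse
connectivity) can be compared; the value/mean ratio of a designated
residue flags pronounced peaks such as candidate mutation sites.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .errors import ValidationError
from .networks import Network


@dataclass
class PathMatrix:
    """All-pairs shortest-path costs; +inf where no path exists."""

    values: np.ndarray
    labels: list[str]
    directed: bool
    semantics: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.labels) != n:
            raise ValidationError("path matrix shape/label mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


@dataclass
class ResidueProfile:
    """Per-residue average shortest-path length.

    ``unreachable_count[j]`` is how many other residues have no path to
    residue j (those pairs are excluded from the mean). ``normalized``
    records whether and how the values were normalized.
    """

    values: np.ndarray
    labels: list[str]
    semantics: str
    unreachable_count: np.ndarray
    normalized: str | None = None
    direction: str = "incoming"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unreachable_count = np.asarray(self.unreachable_count, dtype=int)
        if self.values.shape[0] != len(self.labels):
            raise ValidationError("profile length/label mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    def value_of(self, label: str) -> float:
        try:
            return float(self.values[self.labels.index(label)])
        except ValueError as exc:
            raise ValidationError(f"no residue labelled {label!r}") from exc

    def to_csv(self, path: str | Path, normalized_values: np.ndarray | None = None) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "ordinal": np.arange(self.n_residues),
                "residue_label": self.labels,
                "value": self.values,
                "normalized_value": (
                    normalized_values
                    if normalized_values is not None
                    else self.values / np.nanmean(self.values[np.isfinite(self.values)])
                ),
                "unreachable_count": self.unreachable_count,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, semantics: str, normalized: str | None = None) -> "ResidueProfile":
        import pandas as pd

        df = pd.read_csv(path)
        col = "normalized_value" if normalized else "value"
        return cls(
            values=df[col].to_numpy(float),
            labels=[str(x) for x in df["residue_label"]],
            semantics=semantics,
            unreachable_count=df["unreachable_count"].to_numpy(int),
            normalized=normalized,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def all_pairs_shortest_paths(network: Network) -> PathMatrix:
    """Exact all-pairs shortest-path costs via Dijkstra's algorithm.

    Requires strictly positive edge costs (guaranteed by the network
    builders; re-validated here for externally constructed graphs).
    """
    finite = np.isfinite(network.costs)
    np.fill_diagonal(finite, False)
    if np.any(network.costs[finite] <= 0):
        raise ValidationError("Dijkstra requires strictly positive edge costs")
    rows, cols = np.nonzero(finite)
    graph = csr_matrix(
        (network.costs[rows, cols], (rows, cols)),
        shape=network.costs.shape,
    )
    dist = _dijkstra(graph, directed=network.directed)
    return PathMatrix(
        values=dist,
        labels=list(network.labels),
        directed=network.directed,
        semantics=network.semantics,
    )


def average_shortest_path_profile(
    paths: PathMatrix,
    direction: str = "incoming",
    max_unreachable_fraction: float = 0.10,
) -> ResidueProfile:
    """Average shortest-path length per residue.

    ``incoming`` (default) averages column j over sources i ≠ j — paths
    into the residue; ``outgoing`` averages rows, which differs only for
    directed networks. Self-distances are excluded; unreachable pairs are
    excluded from the mean and counted. A residue no other residue can
    reach gets value +inf with a warning; if more than
    ``max_unreachable_fraction`` of all ordered pairs are unreachable the
    network is considered too fragmented and an error is raised.
    """
    if direction not in ("incoming", "outgoing"):
        raise ValidationError(f"direction must be incoming|outgoing, got {direction!r}")
    D = paths.values if direction == "incoming" else paths.values.T
    n = paths.n_nodes
    off = ~np.eye(n, dtype=bool)
    unreachable = np.isinf(D) & off
    frac = unreachable.sum() / max(n * (n - 1), 1)
    if frac > max_unreachable_fraction:
        raise ValidationError(
            f"{frac:.0%} of residue pairs are unreachable "
            f"(limit {max_unreachable_fraction:.0%}); the network is too sparse"
        )
    values = np.empty(n)
    counts = unreachable.sum(axis=0)
    for j in range(n):
        col = D[:, j][off[:, j]]
        col = col[np.isfinite(col)]
        values[j] = col.mean() if col.size else np.inf
    if np.any(np.isinf(values)):
        warnings.warn(
            f"{int(np.isinf(values).sum())} residue(s) unreachable from all "
            "others; profile value set to +inf",
            stacklevel=2,
        )
    return ResidueProfile(
        values=values,
        labels=list(paths.labels),
        semantics=paths.semantics,
        unreachable_count=counts,
        normalized=None,
        direction=direction,
    )


def normalize_profile(profile: ResidueProfile, method: str = "mean") -> ResidueProfile:
    """Normalize so profiles with different cost units become comparable.

    ``mean``: divide by the mean of the finite values (resulting mean 1);
    ``minmax``: affine map of the finite values onto [0, 1].
    """
    finite = np.isfinite(profile.values)
    vals = profile.values.copy()
    if method == "mean":
        mean = vals[finite].mean()
        if mean <= 0:
            raise ValidationError("profile mean must be positive for mean-normalization")
        vals = vals / mean
    elif method == "minmax":
        lo, hi = vals[finite].min(), vals[finite].max()
        if hi == lo:
            raise ValidationError("degenerate spread: min-max normalization undefined")
        vals = (vals - lo) / (hi - lo)
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return ResidueProfile(
        values=vals,
        labels=list(profile.labels),
        semantics=profile.semantics,
        unreachable_count=profile.unreachable_count.copy(),
        normalized=method,
        direction=profile.direction,
    )


def peak_to_average_ratio(profile: ResidueProfile, residue_label: str) -> float:
    """Ratio of one residue's profile value to the profile mean.

    Invariant to uniform edge-cost scaling and to mean-normalization;
    values well above 1 flag poorly connected residues (peaks), values
    well below 1 flag highly connected ones (e.g. catalytic residues).
    """
    value = profile.value_of(residue_label)
    finite = profile.values[np.isfinite(profile.values)]
    return float(value / finite.mean())


def ratio_report(
    profile: ResidueProfile, residue_labels: list[str], path: str | Path | None = None
) -> dict:
    """Peak/mean ratios for designated residues plus the global extremes."""
    finite_mask = np.isfinite(profile.values)
    order = np.argsort(profile.values[finite_mask])
    finite_labels = [lab for lab, m in zip(profile.labels, finite_mask) if m]
    report = {
        "semantics": profile.semantics,
        "ratios": {lab: peak_to_average_ratio(profile, lab) for lab in residue_labels},
        "best_connected": [finite_labels[i] for i in order[:3]],
        "worst_connected": [finite_labels[i] for i in order[-3:][::-1]],
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
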