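"""Cross-dataset comparison of circadian status and phase via ortholog clusters.

A pre-built ortholog catalogue (cluster id <-> species <-> gene id, plus a
probe-to-gene map per dataset) lets probe-level rhythm calls from two
expression platforms be compared on a common footing.  A cluster is
circadian in a dataset when any of its mapped probes is circadian
(a cluster with several probes still counts once); its phase is the
circular median of its circadian probes' phases.

Phase concordance between two datasets is the squared Pearson correlation
(r^2) of the cluster phase pairs after circular difference minimization:
each pair (a, b) is compared after shifting a by -24, 0 or +24 h so that
|a' - b| <= 12 (e.g. ZT2 vs ZT22 is compared as ZT26 vs ZT22).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circular_median, minimize_circular_pair
from .errors import IntegrityError

__all__ = [
    "OrthologCatalogue",
    "ClusterCall",
    "DatasetComparison",
    "map_probes_to_clusters",
    "minimize_circular_pair",
    "compare_datasets",
    "read_catalogue",
    "write_catalogue",
]


@dataclass
class OrthologCatalogue:
    """Ortholog clusters plus per-dataset probe-to-gene maps.

    ``clusters``: cluster_id -> set of (species_label, gene_id);
    ``probe_maps``: dataset_label -> {probe_id: gene_id}.
    A gene may belong to at most one cluster per species.
    """

    clusters: dict = field(default_factory=dict)
    probe_maps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict = {}
        for cluster_id, members in self.clusters.items():
            for species, gene in members:
                key = (species, gene)
                if key in seen and seen[key] != cluster_id:
                    raise IntegrityError(
                        f"gene {gene} ({species}) appears in clusters {seen[key]} and {cluster_id}"
                    )
                seen[key] = cluster_id
        self._gene_to_cluster = seen

    def cluster_of(self, species: str, gene_id: str):
        return self._gene_to_cluster.get((species, gene_id))

    def add_probe_map(self, dataset_label: str, probe_map: dict) -> None:
        self.probe_maps[dataset_label] = dict(probe_map)


@dataclass(frozen=True)
class ClusterCall:
    """Cluster-level circadian verdict for one dataset."""

    cluster_id: str
    n_probes: int
    circadian: bool
    phase_h: float | None = None


@dataclass(frozen=True)
class DatasetComparison:
    """Shared-cluster overlap counts and phase-concordance r^2."""

    n_shared: int
    n_circadian_a: int
    n_circadian_b: int
    n_circadian_both: int
    r_squared: float | None
    n_phase_pairs: int


def map_probes_to_clusters(
    calls: pd.DataFrame,
    catalogue: OrthologCatalogue,
    dataset_label: str,
    species_label: str,
) -> pd.DataFrame:
    """Aggregate probe-level rhythm calls to cluster level.

    Probes without a catalogue mapping are dropped (their count is in the
    frame's ``attrs['n_unmapped']``).  Output columns: cluster_id, n_probes,
    circadian, phase_h (circular median of circadian member phases, NaN for
    non-circadian clusters).
    """
    probe_map = catalogue.probe_maps.get(dataset_label)
    if probe_map is None:
        raise KeyError(f"catalogue has no probe map for dataset {dataset_label!r}")
    groups: dict[str, dict] = {}
    n_unmapped = 0
    for _, row in calls.iterrows():
        gene = probe_map.get(row["probe_id"])
        cluster = catalogue.cluster_of(species_label, gene) if gene is not None else None
        if cluster is None:
            n_unmapped += 1
            continue
        g = groups.setdefault(cluster, {"n": 0, "phases": []})
        g["n"] += 1
        if bool(row["circadian"]):
            g.setdefault("circadian", True)
            if np.isfinite(row.get("phase_h", np.nan)):
                g["phases"].append(float(row["phase_h"]))
    rows = []
    for cluster_id in sorted(groups):
        g = groups[cluster_id]
        circadian = g.get("circadian", False)
        phase = circular_median(g["phases"]) if circadian and g["phases"] else np.nan
        rows.append(
            {
                "cluster_id": cluster_id,
                "n_probes": g["n"],
                "circadian": circadian,
                "phase_h": phase,
            }
        )
    out = pd.DataFrame(rows, columns=["cluster_id", "n_probes", "circadian", "phase_h"])
    out.attrs["n_unmapped"] = n_unmapped
    return out


def compare_datasets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> DatasetComparison:
    """Compare two cluster-call tables restricted to their shared clusters.

    r^2 is the squared Pearson correlation of phases of clusters circadian
    in both datasets, after circular difference minimization of each pair;
    it is None when fewer than 3 phase pairs exist.
    """
    a = calls_a.set_index("cluster_id")
    b = calls_b.set_index("cluster_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    circ_a = a["circadian"].astype(bool)
    circ_b = b["circadian"].astype(bool)
    both = circ_a & circ_b

    adj_a, adj_b = [], []
    for cluster_id in shared[both]:
        pa, pb = float(a.at[cluster_id, "phase_h"]), float(b.at[cluster_id, "phase_h"])
        if np.isfinite(pa) and np.isfinite(pb):
            aa, bb = minimize_circular_pair(pa, pb)
            # canonical frame: shift the minimized pair so its midpoint lies
            # in [0, 24); differences are untouched and swapping the datasets
            # merely swaps the coordinates, keeping r^2 symmetric
            shift = 24.0 * np.floor(((aa + bb) / 2.0) / 24.0)
            adj_a.append(aa - shift)
            adj_b.append(bb - shift)
    n_pairs = len(adj_a)
    if n_pairs >= 3 and np.std(adj_a) > 0 and np.std(adj_b) > 0:
        r = float(np.corrcoef(adj_a, adj_b)[0, 1])
        r_squared = r * r
    else:
        r_squared = None
    return DatasetComparison(
        n_shared=int(len(shared)),
        n_circadian_a=int(circ_a.sum()),
        n_circadian_b=int(circ_b.sum()),
        n_circadian_both=int(both.sum()),
        r_squared=r_squared,
        n_phase_pairs=n_pairs,
    )


def write_catalogue(catalogue: OrthologCatalogue, clusters_path, probe_maps_dir=None) -> None:
    """Write the cluster table as TSV (cluster_id, species, gene_id)."""
    rows = [
        {"cluster_id": cid, "species": sp, "gene_id": gene}
        for cid, members in sorted(catalogue.clusters.items())
        for sp, gene in sorted(members)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "species", "gene_id"]).to_csv(
        clusters_path, sep="\t", index=False
    )


def read_catalogue(clusters_path) -> OrthologCatalogue:
    """Read a cluster TSV (cluster_id, species, gene_id); probe maps are added separately."""
    df = pd.read_csv(clusters_path, sep="\t", dtype=str)
    clusters: dict[str, set] = {}
    for _, row in df.iterrows():
        clusters.setdefault(row["cluster_id"], set()).add((row["species"], row["gene_id"]))
    return OrthologCatalogue(clusters=clusters)


def read_probe_map(path) -> dict:
    """Read a probe-map TSV (probe_id, gene_id) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.duplicated("probe_id").any():
        dupe = df[df.duplicated("probe_id")].iloc[0]["probe_id"]
        raise IntegrityError(f"probe {dupe} mapped twice")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_probe_map(probe_map: dict, path) -> None:
    pd.DataFrame(
        sorted(probe_map.items()), columns=["probe_id", "gene_id"]
    ).to_csv(path, sep="\t", index=False)
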