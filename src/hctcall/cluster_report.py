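"""Clustering of target genes on peak-category profiles, signal comparisons,
and report export.

Target genes of one regulation direction are encoded as binary rows over the
seven co-occupancy categories and clustered with seeded k-means (k-means++
initialisation, 10 restarts, labels relabelled by descending cluster size).
Signal-strength comparisons between peak groups use the two-sample
Kolmogorov-Smirnov statistic on linear (non-log) values.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special
from sklearn.cluster import KMeans

from .hct import HCTRecord

__all__ = [
    "build_category_matrix",
    "kmeans_cluster",
    "ks_two_sample",
    "export_reports",
]


def build_category_matrix(
    hct: Sequence[HCTRecord], direction: str
) -> pd.DataFrame:
    """Binary genes x 7-categories matrix for HCT of one direction.

    Genes without any categorised peak are excluded (they carry no profile).
    """
    rows = {}
    for rec in hct:
        if rec.direction != direction:
            continue
        if not rec.category_profile:
            continue
        rows[rec.gene_id] = [1 if c in rec.category_profile else 0 for c in range(1, 8)]
    matrix = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"cat{c}" for c in range(1, 8)]
    )
    return matrix.sort_index()


def kmeans_cluster(
    matrix: pd.DataFrame, k: int, seed: int, n_init: int = 10
) -> pd.Series:
    """Seeded k-means over binary category rows.

    Euclidean distance, k-means++ initialisation, best of ``n_init`` restarts;
    labels are renumbered 0..k-1 by descending cluster size (ties by original
    label) so runs are comparable.
    """
    n_distinct = matrix.drop_duplicates().shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy(dtype=float))
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    relabel = {old: new for new, old in enumerate(order)}
    return pd.Series([relabel[x] for x in raw], index=matrix.index, name="cluster")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of the ECDF difference over the pooled data
    points; the p-value uses the asymptotic Kolmogorov distribution with
    effective sample size n m / (n + m).
    """
    x = np.asarray(sorted(x), dtype=float)
    y = np.asarray(sorted(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = x.size * y.size / (x.size + y.size)
    p = float(special.kolmogorov(math.sqrt(en) * d))
    return d, min(1.0, p)


def _frame_to_tsv(frame: pd.DataFrame, path: str, index_label: Optional[str]) -> None:
    frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def export_reports(
    out_dir: str,
    category_counts: Mapping[int, int],
    state_counts: Mapping[str, Mapping[str, int]],
    gene_groups: Mapping[str, Iterable[str]],
    hct: Sequence[HCTRecord],
    clusters: Mapping[str, pd.Series],
    manifest: Mapping,
) -> Dict[str, str]:
    """Write the pipeline's summary bundle to ``out_dir``.

    * ``category_counts.tsv`` — regions per co-occupancy category (1..7).
    * ``state_fractions.tsv`` — per stratum: chromatin-state counts and
      row-normalised fractions (denominator reported alongside).
    * ``gene_groups.tsv`` — gene id, group (P_only / I_only / P_I / other_only).
    * ``hct.tsv`` — gene, direction, evidence, supporting peak count,
      categories present, chromatin summary.
    * ``clusters.tsv`` — gene id, direction, cluster label.
    * ``manifest.json`` — configuration, seeds and input checksums.

    Returns the mapping of logical table name to written path. Output is
    deterministic for identical inputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    cat = pd.DataFrame(
        {"category": list(range(1, 8)),
         "n_regions": [int(category_counts.get(c, 0)) for c in range(1, 8)]}
    )
    paths["category_counts"] = os.path.join(out_dir, "category_counts.tsv")
    _frame_to_tsv(cat, paths["category_counts"], None)

    rows = []
    for stratum in sorted(state_counts):
        counts = state_counts[stratum]
        total = sum(counts.values())
        for state in ("none", "ATAC_only", "K27_only", "ATAC_K27"):
            n = int(counts.get(state, 0))
            rows.append(
                {
                    "stratum": stratum,
                    "state": state,
                    "n": n,
                    "denominator": total,
                    "fraction": (n / total) if total else 0.0,
                }
            )
    paths["state_fractions"] = os.path.join(out_dir, "state_fractions.tsv")
    _frame_to_tsv(pd.DataFrame(rows), paths["state_fractions"], None)

    group_rows = [
        {"gene_id": g, "group": name}
        for name in sorted(gene_groups)
        for g in sorted(gene_groups[name])
    ]
    paths["gene_groups"] = os.path.join(out_dir, "gene_groups.tsv")
    _frame_to_tsv(pd.DataFrame(group_rows, columns=["gene_id", "group"]),
                  paths["gene_groups"], None)

    hct_rows = [
        {
            "gene_id": r.gene_id,
            "direction": r.direction,
            "evidence": r.evidence,
            "n_supporting_peaks": len(r.peak_ids),
            "categories": ",".join(str(c) for c in sorted(r.category_profile)) or ".",
            "chromatin": ",".join(
                f"{p}:{s}" for p, s in sorted(r.chromatin_states.items())
            )
            or ".",
        }
        for r in sorted(hct, key=lambda r: (r.evidence, r.gene_id))
    ]
    paths["hct"] = os.path.join(out_dir, "hct.tsv")
    _frame_to_tsv(
        pd.DataFrame(
            hct_rows,
            columns=[
                "gene_id",
                "direction",
                "evidence",
                "n_supporting_peaks",
                "categories",
                "chromatin",
            ],
        ),
        paths["hct"],
        None,
    )

    cluster_rows = [
        {"gene_id": gene, "direction": direction, "cluster": int(label)}
        for direction in sorted(clusters)
        for gene, label in clusters[direction].sort_index().items()
    ]
    paths["clusters"] = os.path.join(out_dir, "clusters.tsv")
    _frame_to_tsv(
        pd.DataFrame(cluster_rows, columns=["gene_id", "direction", "cluster"]),
        paths["clusters"],
        None,
    )

    paths["manifest"] = os.path.join(out_dir, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def file_checksum(path: str) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
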