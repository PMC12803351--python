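"""Binary trait structure across genomes: presence matrices, pairwise
mutual information, and transporter-repertoire groupings.

Mutual information between presence/absence traits is the plug-in
(maximum-likelihood) estimator in bits,

    MI(X, Y) = sum_xy p(x,y) log2 [ p(x,y) / (p(x) p(y)) ],

over the empirical 2x2 joint table, with 0*log(0) = 0.  No bias
correction is applied; constant traits yield MI 0 with everything by
convention (their entropy is 0).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census import TransporterCensus, TRANSPORTER_CATEGORIES

_CAT_FIELD = {"ABC": "abc_count", "PTS": "pts_count", "MFS": "mfs_count"}


def build_presence_matrix(
    censuses: Iterable[TransporterCensus],
    pathway_calls: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Genome x trait binary matrix from counts and pathway calls.

    Transporter traits are 1 iff the family count is > 0; pathway traits
    copy the completeness call.  ``pathway_calls`` maps genome_id to
    {pathway_id: 0/1} and, when given, must cover exactly the census
    genomes.
    """
    censuses = list(censuses)
    genome_ids = [c.genome_id for c in censuses]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids in census collection")
    data = {
        cat: [int(getattr(c, _CAT_FIELD[cat]) > 0) for c in censuses]
        for cat in TRANSPORTER_CATEGORIES
    }
    mat = pd.DataFrame(data, index=pd.Index(genome_ids, name="genome_id"))
    if pathway_calls is not None:
        if set(pathway_calls) != set(genome_ids):
            raise ValueError(
                "pathway calls and censuses cover different genome sets"
            )
        pw = pd.DataFrame.from_dict(pathway_calls, orient="index").loc[genome_ids]
        mat = pd.concat([mat, pw.astype(int)], axis=1)
    if not mat.isin([0, 1]).all().all():
        raise ValueError("presence matrix must be binary")
    return mat


def _mi_bits(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    joint = np.zeros((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            joint[a, b] = np.sum((x == a) & (y == b))
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            p = joint[a, b]
            if p > 0:
                mi += p * np.log2(p / (px[a] * py[b]))
    return float(max(mi, 0.0))


def binary_entropy(x: Sequence[int]) -> float:
    """Plug-in entropy of a binary vector, in bits."""
    x = np.asarray(x)
    p = float(np.mean(x))
    h = 0.0
    for q in (p, 1 - p):
        if q > 0:
            h -= q * np.log2(q)
    return h


def pairwise_mi(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise mutual information (bits) between all trait columns.

    The diagonal holds each trait's entropy (MI of a trait with itself).
    Requires at least two genomes.
    """
    if len(matrix) < 2:
        raise ValueError("pairwise MI needs at least 2 genomes")
    vals = matrix.to_numpy(dtype=int)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    k = vals.shape[1]
    out = np.zeros((k, k))
    for i in range(k):
        out[i, i] = binary_entropy(vals[:, i])
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = _mi_bits(vals[:, i], vals[:, j])
    return pd.DataFrame(out, index=matrix.columns, columns=matrix.columns)


def repertoire_groups(
    matrix: pd.DataFrame,
    traits: Sequence[str] = TRANSPORTER_CATEGORIES,
) -> dict:
    """Partition genomes by their exact transporter combination.

    Returns a dict with:

    * ``groups`` — mapping from a sorted tuple of carried traits (the
      combination) to the list of member genome ids,
    * ``intersection_sizes`` — combination -> group cardinality,
    * ``set_sizes`` — trait -> number of genomes carrying it.

    Every genome lands in exactly one combination (its exact pattern),
    matching the intersection semantics of an UpSet plot.
    """
    missing = set(traits) - set(matrix.columns)
    if missing:
        raise KeyError(f"traits not in matrix: {sorted(missing)}")
    sub = matrix[list(traits)]
    groups: dict[tuple, list] = {}
    for gid, row in sub.iterrows():
        combo = tuple(t for t in traits if row[t] == 1)
        groups.setdefault(combo, []).append(gid)
    return {
        "groups": groups,
        "intersection_sizes": {c: len(m) for c, m in groups.items()},
        "set_sizes": {t: int(sub[t].sum()) for t in traits},
    }
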