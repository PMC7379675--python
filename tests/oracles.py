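"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a route independent of the library
implementation it checks: naive O(N*M) loops, library graph matching, or
closed-form algebra.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching


def brute_force_assign(events, geometry, capture_radius_nm):
    """O(N*M) nearest-atom deposit assignment with the declared tie rule.

    The nearest atom is found by scanning every atom; ties resolve to the
    atom earliest in (chain_id, residue_seq, atom name) order, matching the
    deterministic ordering of the KD-tree input.
    """
    rows = []
    for nuc_i, nuc in enumerate(geometry.nucleotides):
        for atom in nuc.backbone_atoms:
            rows.append((atom.chain_id, atom.residue_seq, atom.name,
                         atom.position, nuc_i, True))
        for atom in nuc.base_atoms:
            rows.append((atom.chain_id, atom.residue_seq, atom.name,
                         atom.position, nuc_i, False))
    for atom in geometry.obstacle_atoms:
        rows.append((atom.chain_id, atom.residue_seq, atom.name,
                     atom.position, -1, False))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    tally: dict[tuple[int, int], float] = {}
    for event in events:
        if not event.within_volume:
            continue
        best_d, best_row = None, None
        for row in rows:
            d = float(np.linalg.norm(event.position - row[3]))
            if best_d is None or d < best_d - 1e-15:
                best_d, best_row = d, row
        if best_d > capture_radius_nm or not best_row[5]:
            continue
        nuc = geometry.nucleotides[best_row[4]]
        key = (nuc.strand, nuc.bp_index)
        tally[key] = tally.get(key, 0.0) + event.energy_ev
    return tally


def max_matching_dsb(s1_indices, s2_indices, bpt):
    """Maximum number of disjoint opposite-strand pairs within ``bpt``,
    via Hopcroft-Karp maximum bipartite matching (scipy)."""
    n1, n2 = len(s1_indices), len(s2_indices)
    if n1 == 0 or n2 == 0:
        return 0
    rows, cols = [], []
    for i, b1 in enumerate(s1_indices):
        for j, b2 in enumerate(s2_indices):
            if abs(b1 - b2) <= bpt:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n1, n2)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int(np.sum(match >= 0))


def normal_equations_quadratic(doses, p):
    """Closed-form unweighted least squares of p on (D^2, D, 1)."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(p, dtype=float)
    design = np.column_stack([d**2, d, np.ones_like(d)])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    return float(coef[0]), float(coef[1]), float(coef[2])


def brute_force_pairing(geometry, cutoff_nm):
    """Nearest-complement strand pairing by exhaustive loops.

    Returns {strand-2 residue_seq: strand-1 bp_index} for matched
    nucleotides under the greedy closest-claim-first rule (ties to the
    lowest strand-2 residue_seq).
    """

    def anchor(nuc):
        for atom in nuc.backbone_atoms:
            if atom.name == "C1'":
                return atom.position
        return np.mean([a.position for a in nuc.backbone_atoms], axis=0)

    strand1 = sorted(geometry.strand_nucleotides(1),
                     key=lambda n: (n.chain_id, n.residue_seq))
    strand2 = sorted(geometry.strand_nucleotides(2),
                     key=lambda n: (n.chain_id, n.residue_seq))
    pairs = []
    for j, n2 in enumerate(strand2):
        for i, n1 in enumerate(strand1):
            d = float(np.linalg.norm(anchor(n2) - anchor(n1)))
            if d <= cutoff_nm:
                pairs.append((d, n2.residue_seq, j, i))
    pairs.sort()
    taken, out, seen2 = set(), {}, set()
    for _, _, j, i in pairs:
        if j in seen2 or i in taken:
            continue
        seen2.add(j)
        taken.add(i)
        out[strand2[j].residue_seq] = i
    return out
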