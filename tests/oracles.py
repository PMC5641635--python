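"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: the FDR oracle scans
every candidate threshold directly, and the cover oracle enumerates protein
subsets by increasing size.
"""

from itertools import combinations

import numpy as np


def brute_force_fdr(scores, is_decoy, level):
    """Scan all distinct unit scores, most permissive (lowest) first.

    Returns (threshold, retained_target_index_set); threshold is None when
    no candidate threshold reaches the level.
    """
    scores = np.asarray(scores, float)
    is_decoy = np.asarray(is_decoy, bool)
    for t in sorted(set(scores)):
        above = scores >= t
        n_d = int((above & is_decoy).sum())
        n_t = int((above & ~is_decoy).sum())
        if n_d / max(1, n_t) <= level:
            retained = set(np.flatnonzero(above & ~is_decoy))
            return t, retained
    return None, set()


def exhaustive_min_cover_size(prot_to_peps, peptides):
    """Smallest number of proteins whose peptide sets cover ``peptides``."""
    peptides = set(peptides)
    prots = list(prot_to_peps)
    for r in range(1, len(prots) + 1):
        for combo in combinations(prots, r):
            covered = set()
            for p in combo:
                covered |= prot_to_peps[p]
            if covered >= peptides:
                return r
    raise ValueError("peptide set cannot be covered")


def random_fdr_instance(rng, max_units=200):
    """Unit-level scores with ties and a random decoy population."""
    n = int(rng.integers(2, max_units + 1))
    # one-decimal rounding forces score ties reasonably often
    scores = np.round(rng.normal(0, 2, n), 1)
    is_decoy = rng.random(n) < rng.uniform(0.1, 0.6)
    return scores, is_decoy


def random_cover_instance(rng, max_proteins=12, max_peptides=20):
    """Random peptide -> candidate-protein map with non-empty candidates."""
    n_prot = int(rng.integers(1, max_proteins + 1))
    n_pep = int(rng.integers(1, max_peptides + 1))
    prots = [f"P{i}" for i in range(n_prot)]
    pep_to_prots = {}
    for j in range(n_pep):
        k = int(rng.integers(1, n_prot + 1))
        cands = list(rng.choice(prots, size=k, replace=False))
        pep_to_prots[f"pep{j}"] = cands
    return pep_to_prots
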