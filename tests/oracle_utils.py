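"""Independent brute-force oracles shared across test modules."""

import numpy as np

from pocketdiff.chem_core import DEFAULT_VOCAB
from pocketdiff.vina import DEFAULT_WEIGHTS, pair_terms


def brute_force_raw(c, w=DEFAULT_WEIGHTS, vocab=DEFAULT_VOCAB, n_rot=0):
    """Plain double-loop re-implementation of the weighted pair sum."""
    weights = np.array([w.w_gauss1, w.w_gauss2, w.w_repulsion,
                        w.w_hydrophobic, w.w_hbond])
    lig_el = c.ligand.elements(vocab)
    pkt_el = [vocab.elements[i] for i in np.argmax(c.pocket.z, axis=1)]
    total = 0.0
    for i, xi in enumerate(c.ligand.x):
        for j, xj in enumerate(c.pocket.x):
            d = float(np.linalg.norm(xi - xj))
            if d > w.cutoff:
                continue
            ds = d - vocab.vdw_radius[lig_el[i]] - vocab.vdw_radius[pkt_el[j]]
            total += float(pair_terms(ds, lig_el[i], pkt_el[j], vocab) @ weights)
    return total / (1.0 + w.w_rot * n_rot)
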