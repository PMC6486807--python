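"""Bundled example data.

A pairwise genome-rearrangement distance table (breakpoint / inversion
distances over 20 shared collinear blocks) for 15 lycophyte plastomes — two
outgroups (*Huperzia serrata*, *Isoetes flaccida*) and 13 Selaginellaceae —
transcribed from a published comparative analysis. Cells are "BP/IV".
"""

from __future__ import annotations

import numpy as np

from .rearrangement import DistanceTable

__all__ = ["lycophyte_distance_table"]

_TAXA = [
    "H_serrata",
    "I_flaccida",
    "S_lepidophylla",
    "S_vardei",
    "S_indica",
    "S_remotifolia",
    "S_kraussiana",
    "S_lyallii",
    "S_sanguinolenta",
    "S_tamariscina",
    "S_doederleinii",
    "S_moellendorffii",
    "S_pennata",
    "S_bisulcata",
    "S_hainanensis",
]

# lower-triangle rows, cells (BP, IV), taxa order as above
_LOWER = {
    "I_flaccida": [(8, 6)],
    "S_lepidophylla": [(4, 2), (10, 8)],
    "S_vardei": [(5, 3), (10, 9), (5, 3)],
    "S_indica": [(5, 3), (10, 10), (5, 3), (0, 0)],
    "S_remotifolia": [(5, 3), (10, 11), (5, 3), (3, 3), (3, 3)],
    "S_kraussiana": [(5, 3), (10, 12), (5, 3), (3, 3), (3, 3), (0, 0)],
    "S_lyallii": [(5, 3), (10, 13), (5, 3), (3, 3), (3, 3), (0, 0), (0, 0)],
    "S_sanguinolenta": [
        (5, 3), (10, 14), (5, 3), (3, 3), (3, 3), (0, 0), (0, 0), (0, 0),
    ],
    "S_tamariscina": [
        (4, 2), (11, 8), (4, 2), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4),
    ],
    "S_doederleinii": [
        (4, 2), (11, 8), (4, 2), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4),
        (0, 0),
    ],
    "S_moellendorffii": [
        (4, 2), (11, 8), (4, 2), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4),
        (0, 0), (0, 0),
    ],
    "S_pennata": [
        (6, 5), (13, 11), (7, 5), (7, 6), (7, 6), (7, 6), (7, 6), (7, 6), (7, 6),
        (7, 5), (7, 5), (7, 5),
    ],
    "S_bisulcata": [
        (6, 5), (13, 11), (7, 5), (7, 6), (7, 6), (7, 6), (7, 6), (7, 6), (7, 6),
        (7, 5), (7, 5), (7, 5), (0, 0),
    ],
    "S_hainanensis": [
        (6, 5), (12, 10), (6, 5), (7, 6), (7, 6), (7, 6), (7, 6), (7, 6), (7, 6),
        (7, 5), (7, 5), (7, 5), (3, 2), (3, 2),
    ],
}


def lycophyte_distance_table() -> DistanceTable:
    """The bundled 15-taxon pairwise BP/IV distance table."""
    k = len(_TAXA)
    bp = np.zeros((k, k), dtype=int)
    iv = np.zeros((k, k), dtype=int)
    for taxon, cells in _LOWER.items():
        i = _TAXA.index(taxon)
        for j, (b, v) in enumerate(cells):
            bp[i, j] = bp[j, i] = b
            iv[i, j] = iv[j, i] = v
    return DistanceTable(list(_TAXA), bp, iv)
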