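"""Per-element physical parameters and the LCPO coefficient table.

The element table (Lennard-Jones Rmin/2 and ε, intrinsic GB/PB/SASA radius,
mass) is a compact Amber-style set sufficient for the toy archetypes this
package generates and analyses.  Intrinsic radii follow the modified Bondi
convention that accompanies pairwise-descreening GB.

LCPO coefficients are shipped as package data (``data/lcpo.tsv``), keyed by
element and bonded-heavy-neighbour count, and can be replaced wholesale by
passing a different table to :func:`lcpo_coefficients`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

# element → (lj_rmin_half Å, lj_epsilon kcal/mol, intrinsic_radius Å, mass amu)
ELEMENT_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "C": (1.9080, 0.1094, 1.70, 12.011),
    "N": (1.8240, 0.1700, 1.55, 14.007),
    "O": (1.6612, 0.2100, 1.50, 15.999),
    "H": (0.6000, 0.0157, 1.20, 1.008),
    "P": (2.1000, 0.2000, 1.85, 30.974),
    "S": (2.0000, 0.2500, 1.80, 32.06),
}


@lru_cache(maxsize=None)
def _lcpo_table() -> dict[tuple[str, int], tuple[float, float, float, float]]:
    table: dict[tuple[str, int], tuple[float, float, float, float]] = {}
    text = resources.files("endstate").joinpath("data/lcpo.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, n, p1, p2, p3, p4 = line.split("\t")
        table[(el, int(n))] = (float(p1), float(p2), float(p3), float(p4))
    return table


def lcpo_coefficients(element: str, n_heavy_neighbors: int,
                      table: dict | None = None) -> tuple[float, float, float, float]:
    """LCPO P1..P4 for an element with a given bonded-heavy-neighbour count.

    Hydrogens always get (0, 0, 0, 0); heavy elements fall back to the
    largest tabulated neighbour count when the exact count is absent.
    """
    if element == "H":
        return (0.0, 0.0, 0.0, 0.0)
    tab = _lcpo_table() if table is None else table
    key = (element, n_heavy_neighbors)
    if key in tab:
        return tab[key]
    counts = sorted(n for el, n in tab if el == element)
    if not counts:
        raise KeyError(f"no LCPO parameters for element {element!r}")
    nearest = min(counts, key=lambda c: abs(c - n_heavy_neighbors))
    return tab[(element, nearest)]
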