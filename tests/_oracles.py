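"""Independent brute-force oracles used by the tests.

The envelope oracle convolves per-element isotope distributions one atom at a
time with plain Python lists — no numpy, no shared code path with the
implementation beyond the published isotope table and the averagine recipe.
"""

from pyteomics.mass import nist_mass

AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254
_LIGHTEST = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}


def brute_composition(mass: float) -> dict[str, int]:
    scale = mass / AVERAGINE_MASS
    counts = {el: round(scale * n) for el, n in AVERAGINE.items() if el != "H"}
    heavy = sum(nist_mass[el][_LIGHTEST[el]][0] * n for el, n in counts.items())
    counts["H"] = max(0, round((mass - heavy) / nist_mass["H"][1][0]))
    return counts


def _single_atom(element: str, k_max: int) -> list[float]:
    dist = [0.0] * (k_max + 1)
    for a, (_m, ab) in nist_mass[element].items():
        if a == 0 or ab == 0.0:
            continue
        offset = a - _LIGHTEST[element]
        if offset <= k_max:
            dist[offset] += ab
    return dist


def brute_envelope(mass: float, k_max: int) -> list[float]:
    """Isotopologue distribution M+0..M+k_max by per-atom polynomial products."""
    dist = [1.0] + [0.0] * k_max
    for element, n_atoms in brute_composition(mass).items():
        atom = _single_atom(element, k_max)
        for _ in range(n_atoms):
            out = [0.0] * (k_max + 1)
            for i, di in enumerate(dist):
                if di == 0.0:
                    continue
                for j, aj in enumerate(atom):
                    if i + j <= k_max and aj:
                        out[i + j] += di * aj
            dist = out
    total = sum(dist)
    return [d / total for d in dist]
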