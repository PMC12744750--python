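"""Independent brute-force oracles for the equilibrium chemistry.

These deliberately avoid the package's closed forms and Brent root-find:
free-ligand balances are solved by plain bisection, and full speciation by
nested bisection over free concentrations (outer loop on free metal, inner
bisections on each free ligand). A dense-grid minimiser of the total balance
error provides a third, derivative-free route.
"""

from __future__ import annotations

import numpy as np


def bisect_free_ligand(ligand_total: float, free_metal: float, constant: float, n: int,
                       iterations: int = 200) -> float:
    """Bisection on L + n*K*M*L^n - total = 0 over [0, total]."""
    if ligand_total == 0:
        return 0.0

    def f(lig: float) -> float:
        return lig + n * constant * free_metal * lig**n - ligand_total

    lo, hi = 0.0, ligand_total
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def nested_bisection_speciation(metal_total: float, ligands: list[tuple[float, float, int]],
                                iterations: int = 200) -> dict:
    """Full equilibrium by nested bisection.

    ``ligands``: list of (total, constant, n). Outer bisection on free metal
    in [0, metal_total]; at each trial the free ligands come from inner
    bisections. Returns free metal, free ligands, and complex concentrations.
    """
    def metal_balance(m: float) -> float:
        bound = 0.0
        for total, constant, n in ligands:
            # free ligand may be many orders below its total; bisection needs
            # enough halvings for *relative* precision at tiny values
            lig = bisect_free_ligand(total, m, constant, n, iterations=160)
            bound += constant * m * lig**n
        return m + bound - metal_total

    lo, hi = 0.0, metal_total
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if metal_balance(mid) > 0:
            hi = mid
        else:
            lo = mid
    free_metal = 0.5 * (lo + hi)
    free = [bisect_free_ligand(t, free_metal, k, n) for t, k, n in ligands]
    complexes = [k * free_metal * lig**n for (t, k, n), lig in zip(ligands, free)]
    return {"free_metal": free_metal, "free_ligands": free, "complexes": complexes}


def grid_search_speciation(metal_total: float, ligands: list[tuple[float, float, int]],
                           rounds: int = 12, points: int = 81) -> dict:
    """Iteratively refined log-grid minimiser of the absolute metal-balance error."""
    lo, hi = -30.0, np.log10(metal_total)

    def err(log_m: float) -> float:
        m = 10.0**log_m
        bound = sum(
            k * m * bisect_free_ligand(t, m, k, n, iterations=80) ** n
            for t, k, n in ligands
        )
        return abs(m + bound - metal_total)

    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        errors = [err(g) for g in grid]
        i = int(np.argmin(errors))
        lo, hi = grid[max(0, i - 1)], grid[min(points - 1, i + 1)]
    best = 0.5 * (lo + hi)
    m = 10.0**best
    free = [bisect_free_ligand(t, m, k, n) for t, k, n in ligands]
    complexes = [k * m * lig**n for (t, k, n), lig in zip(ligands, free)]
    return {"free_metal": m, "free_ligands": free, "complexes": complexes}
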