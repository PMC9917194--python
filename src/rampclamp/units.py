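"""Unit conventions and physical constants.

The whole package works in Å, ns, pN and kcal/mol. Only the AFM layer uses
nm and Pa; converters below make the switch explicit.

Boltzmann constant: kB = 1.380649e-23 J/K. With 1 pN·Å = 1e-22 J this is
0.138065 pN·Å/K, i.e. kB·T = 42.8 pN·Å at 310 K (≈ 4.28 pN·nm, the familiar
room-temperature scale of single-molecule mechanics).
"""

KB_PN_A_PER_K = 0.0138065 * 10.0  # 0.138065 pN·Å/K
#: Coulomb constant for charges in e and distances in Å, energies in kcal/mol.
COULOMB_KCAL_A_E2 = 332.0636


def kbt_pn_a(temperature_k: float) -> float:
    """Thermal energy kB·T in pN·Å."""
    return KB_PN_A_PER_K * temperature_k


def angstrom_to_nm(x):
    return x * 0.1


def nm_to_angstrom(x):
    return x * 10.0


def pn_per_nm2_to_pa(c):
    """Convert a force/area² fit coefficient from pN/nm² to Pa·(dimensionless δ²).

    F[N] = 1e-12·F[pN], δ[m] = 1e-9·δ[nm]; a quadratic coefficient c with
    F[pN] = c·δ[nm]² therefore corresponds to C[Pa] = 1e6·c.
    """
    return c * 1.0e6
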