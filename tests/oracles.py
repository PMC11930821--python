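"""Independent high-precision oracle for the semi-infinite forward model.

Evaluates the closed form with 50-digit sympy floats, sharing no code with
the numpy implementation under test.
"""

import sympy as sp

PREC = 50


def reff_oracle(n_medium: float) -> sp.Float:
    n = sp.Float(float(n_medium), PREC)
    return (
        -sp.Float("1.440", PREC) / n**2
        + sp.Float("0.710", PREC) / n
        + sp.Float("0.668", PREC)
        + sp.Float("0.0636", PREC) * n
    )


def g1_oracle(tau, bfi, mu_a, mu_s_prime, wavelength_nm, n_medium, rho):
    """g1 at a single lag, 50-digit precision."""
    mu_a = sp.Float(float(mu_a), PREC)
    musp = sp.Float(float(mu_s_prime), PREC)
    lam = sp.Float(float(wavelength_nm), PREC) * sp.Float("1e-7", PREC)
    n = sp.Float(float(n_medium), PREC)
    rho = sp.Float(float(rho), PREC)
    bfi = sp.Float(float(bfi), PREC)
    tau = sp.Float(float(tau), PREC)

    r_eff = reff_oracle(n_medium)
    z0 = 1 / musp
    zb = 2 * (1 + r_eff) / (3 * musp * (1 - r_eff))
    r1 = sp.sqrt(rho**2 + z0**2)
    rb = sp.sqrt(rho**2 + (z0 + 2 * zb) ** 2)
    k0 = 2 * sp.pi * n / lam

    def big_g1(t):
        k = sp.sqrt(3 * mu_a * musp + 6 * musp**2 * k0**2 * bfi * t)
        return sp.exp(-k * r1) / r1 - sp.exp(-k * rb) / rb

    return sp.N(big_g1(tau) / big_g1(sp.Float(0, PREC)), PREC)


def g2_oracle(tau, bfi, beta, **optics):
    g1 = g1_oracle(tau, bfi, **optics)
    return 1 + sp.Float(float(beta), PREC) * g1**2
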