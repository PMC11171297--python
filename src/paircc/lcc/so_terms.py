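"""Spin-orbital linearized-CCSD term list.

The residual is the closed-shell CCSD projected residual truncated to the
terms needed by the linearized theory: source terms (no t1, up to quadratic
t2) and terms linear in t1 (possibly times one t2).  Evaluated at
(t1=0, t2=Tp) it is exactly <mu|Hbar|0> with Hbar = e^-Tp H e^Tp, and its
Jacobian there is exactly <mu|[Hbar, tau_nu]|0>, because [Tp, T'] = 0 and
the dropped terms all carry two or more t1 factors.

The candidate contraction patterns below enumerate every connected pairing
of one integral tensor (f or antisymmetrized v) with the allowed amplitude
content; the rational coefficients were determined by an exact least-squares
match against the brute-force determinant-space residual (see
``paircc.lcc.derive``) and are re-verified against that oracle by the test
suite.  A coefficient of zero means the pattern does not occur in CCSD.
"""

# (name, subscript) factor tuples; i..n occupied, a..g virtual spin orbitals.
SINGLES_CANDIDATES = [
    (("f", "ai"),),
    (("f", "ac"), ("t1", "ic")),
    (("f", "ki"), ("t1", "ka")),
    (("v", "akic"), ("t1", "kc")),
    (("f", "kc"), ("t2", "ikac")),
    (("v", "akcd"), ("t2", "ikcd")),
    (("v", "klic"), ("t2", "klac")),
    (("v", "klcd"), ("t1", "ic"), ("t2", "klad")),
    (("v", "klcd"), ("t1", "ka"), ("t2", "ilcd")),
    (("v", "klcd"), ("t1", "kc"), ("t2", "ilad")),
]

DOUBLES_CANDIDATES = [
    (("v", "ijab"),),
    (("f", "bc"), ("t2", "ijac")),
    (("f", "ac"), ("t2", "ijbc")),
    (("f", "kj"), ("t2", "ikab")),
    (("f", "ki"), ("t2", "jkab")),
    (("v", "klij"), ("t2", "klab")),
    (("v", "abcd"), ("t2", "ijcd")),
    (("v", "kbcj"), ("t2", "ikac")),
    (("v", "kbci"), ("t2", "jkac")),
    (("v", "kacj"), ("t2", "ikbc")),
    (("v", "kaci"), ("t2", "jkbc")),
    (("v", "klcd"), ("t2", "ijcd"), ("t2", "klab")),
    (("v", "klcd"), ("t2", "ikac"), ("t2", "jlbd")),
    (("v", "klcd"), ("t2", "ikbc"), ("t2", "jlad")),
    (("v", "klcd"), ("t2", "ikab"), ("t2", "jlcd")),
    (("v", "klcd"), ("t2", "jkab"), ("t2", "ilcd")),
    (("v", "klcd"), ("t2", "ijac"), ("t2", "klbd")),
    (("v", "klcd"), ("t2", "ijbc"), ("t2", "klad")),
    (("v", "klcd"), ("t2", "ikcd"), ("t2", "jlab")),
    (("v", "klcd"), ("t2", "jkcd"), ("t2", "ilab")),
    (("v", "klcd"), ("t2", "klac"), ("t2", "ijbd")),
    (("v", "klcd"), ("t2", "klbc"), ("t2", "ijad")),
    (("v", "abcj"), ("t1", "ic")),
    (("v", "abci"), ("t1", "jc")),
    (("v", "kbij"), ("t1", "ka")),
    (("v", "kaij"), ("t1", "kb")),
    (("f", "kc"), ("t1", "ka"), ("t2", "ijbc")),
    (("f", "kc"), ("t1", "kb"), ("t2", "ijac")),
    (("f", "kc"), ("t1", "ic"), ("t2", "jkab")),
    (("f", "kc"), ("t1", "jc"), ("t2", "ikab")),
    (("v", "klic"), ("t1", "jc"), ("t2", "klab")),
    (("v", "klic"), ("t1", "ka"), ("t2", "jlbc")),
    (("v", "klic"), ("t1", "kb"), ("t2", "jlac")),
    (("v", "klic"), ("t1", "kc"), ("t2", "jlab")),
    (("v", "kljc"), ("t1", "ic"), ("t2", "klab")),
    (("v", "kljc"), ("t1", "ka"), ("t2", "ilbc")),
    (("v", "kljc"), ("t1", "kb"), ("t2", "ilac")),
    (("v", "kljc"), ("t1", "kc"), ("t2", "ilab")),
    (("v", "akcd"), ("t1", "kb"), ("t2", "ijcd")),
    (("v", "akcd"), ("t1", "ic"), ("t2", "jkbd")),
    (("v", "akcd"), ("t1", "jc"), ("t2", "ikbd")),
    (("v", "akcd"), ("t1", "kc"), ("t2", "ijbd")),
    (("v", "bkcd"), ("t1", "ka"), ("t2", "ijcd")),
    (("v", "bkcd"), ("t1", "ic"), ("t2", "jkad")),
    (("v", "bkcd"), ("t1", "jc"), ("t2", "ikad")),
    (("v", "bkcd"), ("t1", "kc"), ("t2", "ijad")),
]

SINGLES_COEFFS = [
    1.0, 1.0, -1.0, 1.0, 1.0, 0.5, -0.5, -0.5, -0.5, 1.0,
]

DOUBLES_COEFFS = [
    1.0,
    1.0, -1.0, -1.0, 1.0,
    0.5, 0.5,
    1.0, -1.0, -1.0, 1.0,
    0.25, 1.0, -1.0, -0.25, 0.25, -0.25, 0.25, -0.25, 0.25, -0.25, 0.25,
    1.0, -1.0, -1.0, 1.0,
    1.0, -1.0, 1.0, -1.0,
    0.5, -1.0, 1.0, -1.0,
    -0.5, 1.0, -1.0, 1.0,
    -0.5, 1.0, -1.0, 1.0,
    0.5, -1.0, 1.0, -1.0,
]


def singles_terms():
    return [(c, "ia", f) for c, f in zip(SINGLES_COEFFS, SINGLES_CANDIDATES)
            if c != 0.0]


def doubles_terms():
    return [(c, "ijab", f) for c, f in zip(DOUBLES_COEFFS, DOUBLES_CANDIDATES)
            if c != 0.0]
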