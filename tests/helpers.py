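"""Shared test utilities: bucket construction and the exact symbolic
signature oracle."""

from __future__ import annotations

import numpy as np

from moodsig import Bucket


def make_bucket(scores, pid="p1", group=None, start="2014-01-01"):
    """Bucket from an (L, 6) score array with daily timestamps."""
    scores = np.asarray(scores)
    ts = np.datetime64(start) + np.arange(len(scores)).astype("timedelta64[D]")
    return Bucket(participant_id=pid, scores=scores, timestamps=ts, group=group)


def constant_bucket(value=4, L=20, **kw):
    return make_bucket(np.full((L, 6), value, dtype=int), **kw)


def random_path(rng, m, d, scale=1.0):
    return rng.normal(scale=scale, size=(m, d))


def sympy_signature(points, word):
    """Exact signature coefficient of a piecewise-linear path by symbolic
    iterated integration (sympy). Independent of the closed-form engine:
    integrates the nested integrals segment by segment, carrying the inner
    integral as an exact polynomial in the segment-local parameter.

    ``points`` must be exact (ints / fractions / strings sympy can parse).
    """
    import sympy as sp

    pts = [[sp.nsimplify(x) for x in p] for p in points]
    segs = list(zip(pts[:-1], pts[1:]))
    u, v = sp.symbols("u v")
    acc = sp.Integer(1)
    if not word:
        return acc
    Fs = [sp.Integer(1)] * len(segs)  # inner integrand per segment, in u
    for letter in word:
        acc = sp.Integer(0)
        new = []
        for (a, b), F in zip(segs, Fs):
            delta = b[letter - 1] - a[letter - 1]
            prim = sp.integrate(F.subs(u, v) * delta, (v, 0, u))
            new.append(sp.expand(acc + prim))
            acc = sp.expand(acc + prim.subs(u, 1))
        Fs = new
    return acc
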