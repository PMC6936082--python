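"""Independent brute-force evaluators for the enhancement rules.

Deliberately written against the plain-language rule statements, with no
shared helpers from the package: units are (source, aboriginal) pairs in
date order and every decision is spelled out as explicit counting.
Used as the truth table the implementation is checked against.
"""


def oracle_ever(units, base_aboriginal):
    for _src, ab in units:
        if ab:
            return True
    return base_aboriginal


def oracle_most_recent(units, base_aboriginal):
    # units arrive in date order; the last distinct date wins and
    # same-date ties count as Aboriginal when any tied unit is.
    if len(units) == 0:
        return base_aboriginal
    return units[-1][1] if not units[-1][1] else True


def oracle_most_recent_dated(dated_units, base_aboriginal):
    """Variant taking (source, date, aboriginal) with explicit tie pooling."""
    if not dated_units:
        return base_aboriginal
    last = max(d for _s, d, _a in dated_units)
    return any(a for _s, d, a in dated_units if d == last)


def oracle_woe(units, base_aboriginal):
    n = len(units)
    k = sum(1 for _s, a in units if a)
    if n >= 3:
        return k >= 2
    if n in (1, 2):
        return k >= 1
    return base_aboriginal


def oracle_msm(units, base_aboriginal):
    sources = []
    for src, _a in units:
        if src not in sources:
            sources.append(src)
    stage1 = []
    for src in sources:
        sub = [(s, a) for s, a in units if s == src]
        stage1.append(oracle_woe(sub, None))  # every source here has >=1 unit
    if not stage1:
        return base_aboriginal
    return oracle_woe([("stage1", a) for a in stage1], base_aboriginal)
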