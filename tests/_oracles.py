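"""Independent brute-force oracles for the balance definition and the
surgical decision algorithm.

These are written as plain nested conditionals over the raw channel values,
deliberately sharing no code with the package's classifiers or rule engine,
so that agreement between the two is a meaningful check.
"""

ACCEPT = "ACCEPT"


def oracle_balanced(m10, l10, m90, l90):
    """The printed balance definition, evaluated directly."""
    if abs(m10 - l10) >= 15:
        return False
    if abs(m90 - l90) >= 15:
        return False
    for v in (m10, l10, m90, l90):
        if v < 10 or v > 40:
            return False
    return True


def _tight_side(med, lat):
    if med > 40 and lat > 40:
        return "lat" if lat > med else "med"
    if med > 40:
        return "med"
    if lat > 40:
        return "lat"
    if med - lat >= 15:
        return "med"
    if lat - med >= 15:
        return "lat"
    return None


def oracle_action(m10, l10, m90, l90, coronal, ext, done=frozenset()):
    """Next correction per the decision algorithm, hand-coded independently.

    ``done`` is the set of correction names already performed on the case.
    """
    hyper = ext < -2
    small = 0.5 < ext <= 5
    large = ext > 5

    t10 = _tight_side(m10, l10)
    t90 = _tight_side(m90, l90)

    # terminal extension first
    if large:
        if t10 == "lat" and coronal >= 0.5:
            return "ARCUATE_RELEASE"
        if m90 <= 40 and l90 <= 40:
            return "FEMUR_RECUT"
        if (m90 > 40 or l90 > 40) and (m10 > 40 or l10 > 40):
            return "TIBIA_RECUT"
        # flexion tight with acceptable extension loads: falls through to the
        # tightness blocks below
    if small:
        return "POSTERIOR_CAPSULE_RELEASE"
    if hyper:
        return "INSERT_UP_2MM"

    # loose before tight
    if m10 < 10 or l10 < 10 or m90 < 10 or l90 < 10:
        return "INSERT_UP_2MM"

    # lateral tightness
    if t10 == "lat" and t90 != "lat":
        return "ITB_RELEASE" if "ARCUATE_RELEASE" in done else "ARCUATE_RELEASE"
    if t90 == "lat" and t10 != "lat":
        return "POPLITEUS_RELEASE"
    if t10 == "lat" and t90 == "lat":
        return "POPLITEUS_RELEASE" if "ARCUATE_RELEASE" in done else "ARCUATE_RELEASE"

    # medial tightness
    if t10 == "med" and t90 != "med":
        return "MCL_PIECRUST" if coronal < -3 else "FEMUR_RECUT"
    if t90 == "med" and t10 != "med":
        return "MCL_PIECRUST"
    if t10 == "med" and t90 == "med":
        if coronal <= -0.5:
            return "MCL_PIECRUST"
        return "TIBIA_RECUT"

    # balanced loads; alignment may still be out of window
    if coronal < -3:
        return "MCL_PIECRUST"
    if coronal > 3:
        return "ARCUATE_RELEASE"
    return ACCEPT
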