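"""Independent minimal risk-equation evaluators for cross-checking.

A second, separately typed transcription of each model's published
coefficients, evaluated by straight-line formula code with no shared
machinery with the package's declarative engine.  Used only as a test
oracle: agreement to 1e-6 relative guards against transcription or
evaluation defects on either side.
"""

import math


def pce(sex, black, age, tc, hdl, sbp, treated, smoker, diabetes):
    la, lt, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    if sex == "female" and not black:
        lp = (-29.799 * la + 4.884 * la ** 2 + 13.540 * lt - 3.114 * la * lt
              - 13.578 * lh + 3.149 * la * lh
              + (2.019 if treated else 1.957) * ls
              + (7.574 - 1.665 * la) * smoker + 0.661 * diabetes)
        s0, mean = 0.9665, -29.18
    elif sex == "female":
        lp = (17.114 * la + 0.940 * lt - 18.920 * lh + 4.475 * la * lh
              + ((29.291 - 6.432 * la) if treated else (27.820 - 6.087 * la)) * ls
              + 0.691 * smoker + 0.874 * diabetes)
        s0, mean = 0.9533, 86.61
    elif not black:
        lp = (12.344 * la + 11.853 * lt - 2.664 * la * lt - 7.990 * lh
              + 1.769 * la * lh + (1.797 if treated else 1.764) * ls
              + (7.837 - 1.795 * la) * smoker + 0.658 * diabetes)
        s0, mean = 0.9144, 61.18
    else:
        lp = (2.469 * la + 0.302 * lt - 0.307 * lh
              + (1.916 if treated else 1.809) * ls
              + 0.549 * smoker + 0.645 * diabetes)
        s0, mean = 0.8954, 19.54
    return 1.0 - s0 ** math.exp(lp - mean)


def apce(sex, black, age, tc, hdl, sbp, treated, smoker, diabetes):
    ratio = tc / hdl
    b = 1.0 if black else 0.0
    t = 1.0 if treated else 0.0
    if sex == "female":
        lp = (-12.823110 + 0.106501 * age + 0.432440 * b
              + 0.000056 * sbp ** 2 + 0.017666 * sbp + 0.731678 * t
              + 0.943970 * diabetes + 1.009790 * smoker + 0.151318 * ratio
              - 0.008580 * age * b - 0.003647 * sbp * t + 0.006208 * sbp * b
              + 0.152968 * b * t - 0.000153 * age * sbp
              + 0.115232 * b * diabetes - 0.092231 * b * smoker
              + 0.070498 * b * ratio - 0.000173 * b * sbp * t
              - 0.000094 * age * sbp * b)
    else:
        lp = (-11.679980 + 0.064200 * age + 0.482835 * b
              - 0.000061 * sbp ** 2 + 0.038950 * sbp + 2.055533 * t
              + 0.842209 * diabetes + 0.895589 * smoker + 0.193307 * ratio
              - 0.014207 * sbp * t + 0.011609 * sbp * b - 0.119460 * b * t
              + 0.000025 * age * sbp - 0.077214 * b * diabetes
              - 0.226771 * b * smoker - 0.117749 * b * ratio
              + 0.004190 * b * t * sbp - 0.000199 * b * age * sbp)
    return 1.0 / (1.0 + math.exp(-lp))


def framingham_lipids(sex, age, tc, hdl, sbp, treated, smoker, diabetes):
    la, lt, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    if sex == "female":
        lp = (2.32888 * la + 1.20904 * lt - 0.70833 * lh
              + (2.82263 if treated else 2.76157) * ls
              + 0.52873 * smoker + 0.69154 * diabetes)
        s0, mean = 0.95012, 26.1931
    else:
        lp = (3.06117 * la + 1.12370 * lt - 0.93263 * lh
              + (1.99881 if treated else 1.93303) * ls
              + 0.65451 * smoker + 0.57367 * diabetes)
        s0, mean = 0.88936, 23.9802
    return 1.0 - s0 ** math.exp(lp - mean)


def framingham_bmi(sex, age, bmi, sbp, treated, smoker, diabetes):
    la, lb, ls = math.log(age), math.log(bmi), math.log(sbp)
    if sex == "female":
        lp = (2.72107 * la + 0.51125 * lb
              + (2.88267 if treated else 2.81291) * ls
              + 0.61868 * smoker + 0.77763 * diabetes)
        s0, mean = 0.94833, 26.0145
    else:
        lp = (3.11296 * la + 0.79277 * lb
              + (1.92672 if treated else 1.85508) * ls
              + 0.70953 * smoker + 0.53160 * diabetes)
        s0, mean = 0.88431, 23.9388
    return 1.0 - s0 ** math.exp(lp - mean)


def who_lipids(sex, age, tc_mmoll, sbp, smoker, diabetes):
    a = age - 60.0
    s = sbp - 120.0
    c = tc_mmoll - 6.0
    if sex == "female":
        lp = (0.0779636 * a + 0.6010619 * smoker + 0.0112106 * s
              + 0.8460193 * diabetes + 0.1319427 * c
              - 0.0110117 * a * smoker - 0.0000649 * a * s
              - 0.0175542 * a * diabetes - 0.0014626 * a * c)
        s0 = 0.944
    else:
        lp = (0.0719227 * a + 0.4164492 * smoker + 0.0128421 * s
              + 0.6061665 * diabetes + 0.1543391 * c
              - 0.0045741 * a * smoker - 0.0001813 * a * s
              - 0.0129724 * a * diabetes - 0.0016854 * a * c)
        s0 = 0.930
    return 1.0 - s0 ** math.exp(lp)


def who_bmi(sex, age, bmi, sbp, smoker):
    a = age - 60.0
    s = sbp - 120.0
    b = bmi - 25.0
    if sex == "female":
        lp = (0.0779636 * a + 0.6010619 * smoker + 0.0112106 * s
              + 0.0430172 * b - 0.0110117 * a * smoker
              - 0.0000649 * a * s - 0.0004769 * a * b)
        s0 = 0.942
    else:
        lp = (0.0719227 * a + 0.4164492 * smoker + 0.0128421 * s
              + 0.0462304 * b - 0.0045741 * a * smoker
              - 0.0005048 * a * b)
        s0 = 0.928
    return 1.0 - s0 ** math.exp(lp)


MGDL_PER_MMOLL = 38.67


def evaluate(model_id, record, ancestry="black"):
    """Evaluate a model on a ParticipantRecord-like object."""
    black = ancestry == "black"
    sbp = (record.sbp2 + record.sbp3) / 2.0
    common = dict(age=record.age, sbp=sbp, smoker=int(record.smoker),
                  diabetes=int(record.diabetes))
    if model_id == "pce":
        return pce(record.sex, black, tc=record.total_cholesterol,
                   hdl=record.hdl, treated=record.bp_treated, **common)
    if model_id == "apce":
        return apce(record.sex, black, tc=record.total_cholesterol,
                    hdl=record.hdl, treated=record.bp_treated, **common)
    if model_id == "framingham_lipids":
        return framingham_lipids(record.sex, tc=record.total_cholesterol,
                                 hdl=record.hdl, treated=record.bp_treated,
                                 **common)
    if model_id == "framingham_bmi":
        return framingham_bmi(record.sex, bmi=record.bmi,
                              treated=record.bp_treated, **common)
    if model_id == "who_lipids":
        return who_lipids(record.sex, record.age,
                          record.total_cholesterol / MGDL_PER_MMOLL, sbp,
                          int(record.smoker), int(record.diabetes))
    if model_id == "who_bmi":
        return who_bmi(record.sex, record.age, record.bmi, sbp,
                       int(record.smoker))
    raise KeyError(model_id)
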