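"""Independent scalar re-implementation of the color math, used as a
test oracle. Pure Python + math module only — deliberately shares no
code with the package's vectorized implementation."""

import math

_M = (
    (0.4124, 0.3575, 0.1804),
    (0.2126, 0.7151, 0.0721),
    (0.0193, 0.1191, 0.9502),
)
_WHITE = (95.047, 100.0, 108.883)
_D = 6.0 / 29.0


def f_scalar(t):
    if t > _D**3:
        return t ** (1.0 / 3.0)
    return t / 3.0 * (29.0 / 6.0) ** 2 + 4.0 / 29.0


def rgb8_to_lab_scalar(r, g, b):
    frac = (r / 255.0, g / 255.0, b / 255.0)
    xyz = [100.0 * sum(_M[i][j] * frac[j] for j in range(3)) for i in range(3)]
    fx = f_scalar(xyz[0] / _WHITE[0])
    fy = f_scalar(xyz[1] / _WHITE[1])
    fz = f_scalar(xyz[2] / _WHITE[2])
    return (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def pearson_scalar(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
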