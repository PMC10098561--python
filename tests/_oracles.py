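"""Independent single-loop oracles for the window features.

Deliberately written as plain Python loops straight off the defining sums,
sharing no code with the package implementation.
"""

import math


def iemg(x):
    total = 0.0
    for v in x:
        total += abs(v)
    return total


def mav(x):
    return iemg(x) / len(x)


def mav1(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        w = 1.0 if 0.25 * n <= i <= 0.75 * n else 0.5
        total += w * abs(v)
    return total / n


def rms(x):
    total = 0.0
    for v in x:
        total += v * v
    return math.sqrt(total / len(x))


def aac(x):
    total = 0.0
    for i in range(len(x) - 1):
        total += abs(x[i + 1] - x[i])
    return total / len(x)


def zc(x, threshold=0.0):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= threshold:
            count += 1
    return count


def ssc(x, threshold=0.0):
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= threshold:
            count += 1
    return count


def wamp(x, threshold=0.0):
    count = 0
    for i in range(len(x) - 1):
        if abs(x[i] - x[i + 1]) >= threshold:
            count += 1
    return count


def wl(x):
    total = 0.0
    for i in range(len(x) - 1):
        total += abs(x[i + 1] - x[i])
    return total


def sd(x):
    n = len(x)
    mean = sum(x) / n
    var = 0.0
    for v in x:
        var += (v - mean) ** 2
    return math.sqrt(var / n)


ALL = {
    "IEMG": iemg,
    "MAV": mav,
    "MAV1": mav1,
    "RMS": rms,
    "AAC": aac,
    "ZC": zc,
    "SSC": ssc,
    "WAMP": wamp,
    "WL": wl,
    "SD": sd,
}
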