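"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own code paths: NMI by explicit
contingency counting, modularity by a double loop, and the modularity
optimum by exhaustive set-partition enumeration.
"""

import math
from collections import Counter


def nmi_oracle(a, b):
    """Contingency-table normalized MI (2*MI / (Ha + Hb), natural log)."""
    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    mi = 0.0
    for (x, y), c in joint.items():
        p = c / n
        mi += p * math.log(p / ((pa[x] / n) * (pb[y] / n)))
    ha = -sum((c / n) * math.log(c / n) for c in pa.values())
    hb = -sum((c / n) * math.log(c / n) for c in pb.values())
    if ha == 0 or hb == 0:
        return 0.0
    return 2 * mi / (ha + hb)


def all_partitions(n):
    """Enumerate every set partition of range(n) as a label vector."""
    if n == 1:
        yield [0]
        return
    for rest in all_partitions(n - 1):
        k = max(rest) + 1
        for c in range(k + 1):
            yield rest + [c]


def q_oracle(S, labels, gamma):
    """Constant-Potts modularity over ordered pairs, explicit double loop."""
    n = len(labels)
    q = 0.0
    for r in range(n):
        for s in range(n):
            if r != s and labels[r] == labels[s]:
                q += S[r, s] - gamma
    return q
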