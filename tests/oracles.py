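"""Independent reference implementations used as oracles in tests.

These deliberately avoid the production code paths: event segmentation is
done by enumerating all candidate frame intervals and checking validity
and maximality directly against the rule's definition, rather than by the
production single-pass scan.
"""

import numpy as np


def enumerate_events(frames, c_dist, c_speed, c_conf, tolerance_enabled):
    """All maximal valid intervals of a criterion sequence.

    A frame is eligible if all three criteria hold, or (tolerance) exactly
    one fails while both global neighbors exist, are frame-contiguous and
    fully qualify.  An interval is valid if every frame is eligible and
    frame numbers are consecutive; it is reported if valid and not
    extendable on either side.  Returns (start, end, n_frames, n_tolerated)
    tuples.
    """
    frames = list(frames)
    n = len(frames)
    all3 = [bool(c_dist[i] and c_speed[i] and c_conf[i]) for i in range(n)]
    nmet = [int(c_dist[i]) + int(c_speed[i]) + int(c_conf[i]) for i in range(n)]

    def eligible(i):
        if all3[i]:
            return True
        if not tolerance_enabled:
            return False
        return (
            nmet[i] == 2
            and 0 < i < n - 1
            and all3[i - 1]
            and all3[i + 1]
            and frames[i] - frames[i - 1] == 1
            and frames[i + 1] - frames[i] == 1
        )

    elig = [eligible(i) for i in range(n)]

    def valid(a, b):
        if not all(elig[a : b + 1]):
            return False
        return all(frames[i] == frames[i - 1] + 1 for i in range(a + 1, b + 1))

    out = []
    for a in range(n):
        for b in range(a, n):
            if not valid(a, b):
                continue
            left = a > 0 and elig[a - 1] and frames[a] - frames[a - 1] == 1
            right = b < n - 1 and elig[b + 1] and frames[b + 1] - frames[b] == 1
            if not left and not right:
                n_tol = sum(1 for i in range(a, b + 1) if elig[i] and not all3[i])
                out.append((frames[a], frames[b], b - a + 1, n_tol))
    return out


def random_criteria(rng, n, p=0.7, gap_p=0.05):
    """A random criterion sequence with occasional frame gaps."""
    frames = [0]
    for _ in range(n - 1):
        frames.append(frames[-1] + (2 if rng.random() < gap_p else 1))
    frames = np.array(frames)
    cd = rng.random(n) < p
    cs = rng.random(n) < p
    cc = rng.random(n) < p
    return frames, cd, cs, cc


def ttest_closed_form(a, b):
    """Textbook unpaired equal-variance t-test: t and two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p
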