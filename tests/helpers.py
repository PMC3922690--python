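import numpy as np
from scipy.optimize import linear_sum_assignment


def matched_cosines(H, H_true):
    """Min-cost pairing of basis rows by cosine distance; returns cosines."""

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    C = np.array([[1 - cos(h, t) for t in H_true] for h in H])
    ri, ci = linear_sum_assignment(C)
    return np.array([1 - C[i, j] for i, j in zip(ri, ci)])
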