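import numpy as np


def random_rotation(rng, reflect=False):
    """Random orthogonal 3x3 via QR; optionally force a reflection."""
    Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if reflect != (np.linalg.det(Q) < 0):
        Q[:, 0] = -Q[:, 0]
    return Q
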