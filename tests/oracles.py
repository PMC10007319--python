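"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written with plain Python loops and
``math`` so it shares no code path with the package.
"""

import math


def shock_filter_oracle(values, dt=0.5, max_iters=200, smoothing_sigma=1.0,
                        convergence_tol=1e-3):
    """Per-sample scalar reference for the upwind shock-filter iteration."""
    u = [float(v) for v in values]
    n = len(u)
    rng = max(u) - min(u)
    if rng == 0.0:
        return u
    tol = convergence_tol * rng
    if smoothing_sigma <= 0:
        kernel = [1.0]
    else:
        radius = max(1, int(4.0 * smoothing_sigma + 0.5))
        kernel = [
            math.exp(-0.5 * ((i - radius) / smoothing_sigma) ** 2)
            for i in range(2 * radius + 1)
        ]
        total = 0.0
        for v in kernel:
            total = total + v
        kernel = [v / total for v in kernel]
    half = len(kernel) // 2
    for _ in range(max_iters):
        dm = [0.0] + [u[i] - u[i - 1] for i in range(1, n)]
        dp = [u[i + 1] - u[i] for i in range(n - 1)] + [0.0]
        uxx = [dp[i] - dm[i] for i in range(n)]
        uxx[0] = 0.0
        uxx[-1] = 0.0
        s = []
        for i in range(n):
            acc = 0.0
            for k in range(len(kernel)):
                j = i + k - half
                j = 0 if j < 0 else (n - 1 if j > n - 1 else j)
                acc = acc + kernel[k] * uxx[j]
            s.append(acc)
        du = [0.0] * n
        for i in range(n):
            if s[i] > 0.0:
                du[i] = -max(max(dm[i], 0.0), -min(dp[i], 0.0)) * dt
            elif s[i] < 0.0:
                du[i] = max(max(dp[i], 0.0), -min(dm[i], 0.0)) * dt
        du[0] = 0.0
        du[-1] = 0.0
        for i in range(n):
            u[i] = u[i] + du[i]
        if max(abs(d) for d in du) < tol:
            break
    return u


def total_variation(values):
    return sum(abs(values[i + 1] - values[i]) for i in range(len(values) - 1))


def row_means(matrix):
    return [sum(row) / len(row) for row in matrix]


def col_means(matrix):
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    return [sum(matrix[i][j] for i in range(n_rows)) / n_rows for j in range(n_cols)]


def autocorrelation(values):
    """Normalised mean-removed autocorrelation by explicit double loop."""
    n = len(values)
    mean = sum(values) / n
    x = [v - mean for v in values]
    denom = sum(v * v for v in x)
    out = []
    for lag in range(n):
        out.append(sum(x[i] * x[i + lag] for i in range(n - lag)) / denom)
    return out


def _inside_ellipse(dx, dy, a, b):
    return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0


def grey_opening(matrix, a, b):
    """Grayscale opening with an elliptical flat structuring element."""
    n_rows, n_cols = len(matrix), len(matrix[0])
    offsets = [
        (dy, dx)
        for dy in range(-b, b + 1)
        for dx in range(-a, a + 1)
        if _inside_ellipse(dx, dy, a, b)
    ]

    def erode(mat):
        return [
            [min(clamp_mat(mat, i + dy, j + dx, n_rows, n_cols) for dy, dx in offsets)
             for j in range(n_cols)]
            for i in range(n_rows)
        ]

    def dilate(mat):
        return [
            [max(clamp_mat(mat, i + dy, j + dx, n_rows, n_cols) for dy, dx in offsets)
             for j in range(n_cols)]
            for i in range(n_rows)
        ]

    return dilate(erode(matrix))


def clamp_mat(mat, i, j, n_rows, n_cols):
    # symmetric ("reflect") border: d c b a | a b c d
    if i < 0:
        i = -i - 1
    if i > n_rows - 1:
        i = 2 * n_rows - 1 - i
    if j < 0:
        j = -j - 1
    if j > n_cols - 1:
        j = 2 * n_cols - 1 - j
    return mat[i][j]
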