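"""Test-only oracles that are independent of the package's own solver."""

import subprocess
from pathlib import Path

import numpy as np
import pandas as pd

_GLMNET_SCRIPT = """
suppressMessages(library(glmnet))
args <- commandArgs(trailingOnly = TRUE)
x <- as.matrix(read.csv(args[1]))
y <- scan(args[2], quiet = TRUE)
lam <- scan(args[3], quiet = TRUE)
fit <- glmnet(x, y, family = "poisson", alpha = 1, lambda = lam,
              standardize = FALSE, thresh = 1e-14, maxit = 1e7)
co <- as.matrix(coef(fit))
write.csv(co, args[4], row.names = FALSE)
"""


def glmnet_poisson_lasso(X, y, lambdas, workdir):
    """Fit an L1-penalized Poisson regression with R glmnet.

    Returns (intercepts, coefs) with coefs of shape (n_lambda, p);
    glmnet minimizes (1/n) * negative log-likelihood + lambda * ||beta||_1
    with an unpenalized intercept, matching the package's objective for
    singleton groups with unit group weights.
    """
    workdir = Path(workdir)
    xp, yp = workdir / "x.csv", workdir / "y.txt"
    lp, op = workdir / "lam.txt", workdir / "coef.csv"
    pd.DataFrame(np.asarray(X)).to_csv(xp, index=False)
    np.savetxt(yp, np.asarray(y))
    lam = np.sort(np.atleast_1d(np.asarray(lambdas, dtype=float)))[::-1]
    np.savetxt(lp, lam)
    script = workdir / "fit.R"
    script.write_text(_GLMNET_SCRIPT)
    subprocess.run(
        ["Rscript", "--vanilla", str(script), str(xp), str(yp), str(lp),
         str(op)],
        check=True, capture_output=True, text=True,
    )
    co = pd.read_csv(op).to_numpy()  # (p+1, n_lambda)
    return lam, co[0], co[1:].T


def poisson_lasso_objective(X, y, b0, beta, lam):
    """(1/n) sum(mu - y*eta) + lam * ||beta||_1 (constant terms of the
    log-likelihood dropped)."""
    eta = b0 + X @ beta
    return float(np.mean(np.exp(eta) - y * eta) + lam * np.abs(beta).sum())
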