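"""Re-derive the synthetic-cohort generator's frozen default constants.

Solves, by deterministic Gauss-Hermite quadrature:

1. the risk-factor equicorrelation giving P(at least one factor) = 0.558
   from the published marginals, and
2. the latent-distress shifts and instrument cut-points under which the
   two-stage Whooley->PHQ-9 strategy attains the published operating
   characteristics (whole sample 70.6%/89.5%, high-risk subgroup
   74.2%/85.0%), single-stage Whooley specificity is 68% in the high-risk
   group, and the EPDS cut-offs give ~80% / ~62% high-risk sensitivity.

The printed solution is what `casefind.cohort.GeneratorConfig` ships as
defaults; run this script after changing any calibration target.
"""

import numpy as np
from scipy import optimize
from scipy.stats import norm

from casefind.cohort import calibrate_association

P_HIGH, PREV_HIGH, PREV_WHOLE = 0.558, 0.171, 0.103
PREV_LOW = (PREV_WHOLE - P_HIGH * PREV_HIGH) / (1 - P_HIGH)
SENS_HIGH, SENS_WHOLE = 0.742, 0.706
SPEC_HIGH, SPEC_WHOLE = 0.850, 0.895
WHOOLEY_SPEC_HIGH = 0.68
P_MODSEV, DELTA, SIG = 0.30, 0.5, 0.7

# stratum shares within the depressed / non-depressed populations
sh_dep = P_HIGH * PREV_HIGH / (P_HIGH * PREV_HIGH + (1 - P_HIGH) * PREV_LOW)
sh_nd = P_HIGH * (1 - PREV_HIGH) / (P_HIGH * (1 - PREV_HIGH) + (1 - P_HIGH) * (1 - PREV_LOW))
sens_low = (SENS_WHOLE - sh_dep * SENS_HIGH) / (1 - sh_dep)
spec_low = (SPEC_WHOLE - sh_nd * SPEC_HIGH) / (1 - sh_nd)

gx, gw = np.polynomial.hermite_e.hermegauss(81)
gw = gw / gw.sum()


def p_chain(m, t_w, t_p):
    z = m + gx
    return float(np.sum(gw * norm.cdf((z - t_w) / SIG) * norm.cdf((z - t_p) / SIG)))


def p_single(m, t):
    return float(norm.sf((t - m) / np.hypot(1.0, SIG)))


def sens_chain(m, t_w, t_p):
    return (1 - P_MODSEV) * p_chain(m, t_w, t_p) + P_MODSEV * p_chain(m + DELTA, t_w, t_p)


def residuals(x):
    t_w, t_p, alpha, mu, gamma = x
    return [
        p_chain(0.0, t_w, t_p) - (1 - spec_low),
        p_chain(alpha, t_w, t_p) - (1 - SPEC_HIGH),
        sens_chain(mu, t_w, t_p) - sens_low,
        sens_chain(mu + alpha + gamma, t_w, t_p) - SENS_HIGH,
        p_single(alpha, t_w) - (1 - WHOOLEY_SPEC_HIGH),
    ]


def main():
    rho = calibrate_association(P_HIGH, (0.028, 0.353, 0.340, 0.182))
    print(f"risk_factor_association = {rho:.7f}")

    sol = optimize.least_squares(residuals, x0=[1.0, 1.2, 0.4, 0.6, 0.8],
                                 bounds=([-2, -2, 0, -1, 0], [4, 4, 3, 4, 4]),
                                 xtol=1e-14, ftol=1e-14)
    t_w, t_p, alpha, mu, gamma = sol.x
    print(f"whooley cutpoint        = {t_w:.6f}")
    print(f"phq9 cutpoint           = {t_p:.6f}")
    print(f"distress_highrisk_shift = {alpha:.6f}")
    print(f"distress_mild           = {mu:.6f}")
    print(f"distress_highrisk_dep_shift = {gamma:.6f}")
    print("max residual:", max(abs(r) for r in residuals(sol.x)))

    def epds_sens_high(t):
        return ((1 - P_MODSEV) * p_single(mu + alpha + gamma, t)
                + P_MODSEV * p_single(mu + alpha + gamma + DELTA, t))

    t10 = optimize.brentq(lambda t: epds_sens_high(t) - 0.80, -3, 5)
    t13 = optimize.brentq(lambda t: epds_sens_high(t) - 0.62, -3, 5)
    print(f"epds cutpoints          = ({t10:.6f}, {t13:.6f})")


if __name__ == "__main__":
    main()
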