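# Independent reference implementation of the SPEI / SPI standardization
# recipes, used once to freeze oracle fixtures:
#
#   Rscript tests/fixtures/make_reference.R
#
# Reads index_oracle_input.csv (synthetic monthly water balance D and
# precipitation), computes
#   * SPEI at timescales 1 and 12: k-month backward sums, per-calendar-month
#     three-parameter log-logistic fitted by unbiased probability-weighted
#     moments (moments w_s = E[X (1-F)^s]); months with negative sample
#     L-skewness are standardized through the mirrored sample;
#   * SPI at timescale 2: k-month precipitation sums, per-calendar-month
#     two-parameter gamma by maximum likelihood on the positive values with
#     a point mass q at zero, H(x) = q + (1-q) G(x);
# and maps cumulative probabilities to standard-normal quantiles.
# Writes index_oracle_expected.csv.

suppressMessages(library(stats))

agg <- function(x, k) {
  n <- length(x)
  out <- rep(NA_real_, n)
  for (m in k:n) out[m] <- sum(x[(m - k + 1):m])
  out
}

pwm <- function(x) {
  x <- sort(x)
  n <- length(x)
  i <- seq_len(n)
  w0 <- mean(x)
  w1 <- sum((n - i) / (n - 1) * x) / n
  w2 <- sum((n - i) * (n - i - 1) / ((n - 1) * (n - 2)) * x) / n
  c(w0, w1, w2)
}

loglogistic_prob <- function(values, ref) {
  w <- pwm(ref)
  beta <- (2 * w[2] - w[1]) / (6 * w[2] - w[1] - 6 * w[3])
  g1g2 <- gamma(1 + 1 / beta) * gamma(1 - 1 / beta)
  alpha <- (w[1] - 2 * w[2]) * beta / g1g2
  gam <- w[1] - alpha * g1g2
  stopifnot(beta > 1, alpha > 0)
  p <- ifelse(values > gam, 1 / (1 + (alpha / (values - gam))^beta), 0)
  p
}

spei_column <- function(d, months, k) {
  a <- agg(d, k)
  z <- rep(NA_real_, length(a))
  for (cm in 1:12) {
    sel <- which(!is.na(a) & months == cm)
    ref <- a[sel]
    w <- pwm(ref)
    tau3 <- (w[1] - 6 * w[2] + 6 * w[3]) / (w[1] - 2 * w[2])
    if (tau3 < 0) {
      p <- 1 - loglogistic_prob(-a[sel], -ref)
    } else {
      p <- loglogistic_prob(a[sel], ref)
    }
    z[sel] <- qnorm(pmin(pmax(p, pnorm(-6)), pnorm(6)))
  }
  z
}

gamma_negll <- function(par, x) {
  -sum(dgamma(x, shape = exp(par[1]), rate = exp(par[2]), log = TRUE))
}

spi_column <- function(p, months, k) {
  a <- agg(p, k)
  z <- rep(NA_real_, length(a))
  for (cm in 1:12) {
    sel <- which(!is.na(a) & months == cm)
    ref <- a[sel]
    pos <- ref[ref > 0]
    q <- 1 - length(pos) / length(ref)
    init <- c(log(mean(pos)^2 / var(pos)), log(mean(pos) / var(pos)))
    fit <- optim(init, gamma_negll, x = pos, method = "Nelder-Mead",
                 control = list(reltol = 1e-12, maxit = 5000))
    shp <- exp(fit$par[1]); rte <- exp(fit$par[2])
    x <- a[sel]
    h <- ifelse(x > 0, q + (1 - q) * pgamma(x, shape = shp, rate = rte), q)
    z[sel] <- qnorm(pmin(pmax(h, pnorm(-6)), pnorm(6)))
  }
  z
}

here <- dirname(sub("--file=", "", grep("--file=", commandArgs(FALSE), value = TRUE)))
inp <- read.csv(file.path(here, "index_oracle_input.csv"))
out <- data.frame(
  year = inp$year, month = inp$month,
  spei_k1 = spei_column(inp$d_mm, inp$month, 1),
  spei_k12 = spei_column(inp$d_mm, inp$month, 12),
  spi_k2 = spi_column(inp$precip_mm, inp$month, 2)
)
write.csv(format(out, digits = 8, trim = TRUE),
          file.path(here, "index_oracle_expected.csv"),
          row.names = FALSE, quote = FALSE)
cat("wrote", file.path(here, "index_oracle_expected.csv"), "\n")
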