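# Generates the frozen reference values in mixomics_oracle.json from the
# fixture matrices in this directory, using the mixOmics package as an
# independent implementation. Run once from the repository root:
#   Rscript tests/oracles/generate_mixomics_oracle.R
suppressMessages(library(mixOmics))
suppressMessages(library(jsonlite))

dir <- "tests/oracles"
X <- as.matrix(read.csv(file.path(dir, "X.csv"), row.names = 1))
Y <- as.matrix(read.csv(file.path(dir, "Y.csv"), row.names = 1))
counts <- as.matrix(read.csv(file.path(dir, "counts.csv"), row.names = 1))

out <- list()

# centered log-ratio with +1 offset (compositional preprocessing)
clr <- logratio.transfo(counts + 1, logratio = "CLR")
out$clr <- matrix(as.numeric(clr), nrow = nrow(counts))

# dense PLS, both deflation modes, 2 components
for (mode in c("regression", "canonical")) {
  fit <- pls(X, Y, ncomp = 2, mode = mode, scale = TRUE)
  out[[paste0("pls_", mode)]] <- list(
    loadings_X = unname(fit$loadings$X),
    loadings_Y = unname(fit$loadings$Y),
    variates_X = unname(fit$variates$X),
    variates_Y = unname(fit$variates$Y))
}

# sparse PLS, keepX = c(2, 2), keepY = c(3, 2)
sfit <- spls(X, Y, ncomp = 2, mode = "regression",
             keepX = c(2, 2), keepY = c(3, 2), scale = TRUE)
out$spls <- list(loadings_X = unname(sfit$loadings$X),
                 loadings_Y = unname(sfit$loadings$Y))

writeLines(toJSON(out, digits = I(12), auto_unbox = TRUE),
           file.path(dir, "mixomics_oracle.json"))
cat("wrote", file.path(dir, "mixomics_oracle.json"), "\n")
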