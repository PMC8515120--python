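# Synthetic gut phenylpropanoid metabolic module set (20 modules).
# These definitions are SYNTHETIC stand-ins with invented ortholog content,
# written in KEGG module syntax (steps separated by spaces, alternatives by
# commas, complexes by '+', optional components by '-', groups in
# parentheses). Replace this file with curated definitions to analyse real
# data; the block format is ID<tab>NAME then one definition line.

MC0001	phenylalanine ammonia-lyase route (synthetic)
K00101 K00102,K00103

MC0002	quinate degradation (synthetic)
K00104+K00105 K00106

MC0003	shikimate to protocatechuate (synthetic)
(K00107+K00108),K00109 K00110

MC0004	cinnamate conversion (synthetic)
K00111 K00112,K00113 K00114+K00115

MC0005	coumarate degradation (synthetic)
K00116,K00117 K00118 K00119+K00120

MC0006	chlorogenate hydrolysis (synthetic)
K00121 K00122

MC0007	ferulate demethylation (synthetic)
K00123 K00124,K00125 K00126

MC0008	caffeate reduction (synthetic)
K00127+K00128,K00129 K00130

MC0009	benzoyl-CoA ligation (synthetic)
(K00131,K00132)+K00133 K00134

MC0010	catechol ortho-cleavage (synthetic)
K00135 K00136 K00137,K00138

MC0011	4-hydroxybenzoate decarboxylation (synthetic)
K00139+K00140-K00141 K00142

MC0012	phloretin hydrolysis (synthetic)
K00143 K00144,K00145

MC0013	rare cinnamoyl esterase (synthetic, low prevalence)
K00150 K00151,K00152

MC0014	phenylpropanoate CoA transfer (synthetic)
K00153,K00154 K00155

MC0015	hydroxycinnamate transport (synthetic)
K00156+K00157 K00158,K00159

MC0016	vanillate demethylase (synthetic)
K00160 K00161+K00162

MC0017	protocatechuate decarboxylation (synthetic)
K00163,K00164 K00165 K00166

MC0018	benzaldehyde oxidation (synthetic)
K00167 K00168,K00169,K00170

MC0019	phenylacetate ring cleavage (synthetic)
K00171+K00172 (K00173,K00174)+K00175

MC0020	hippurate hydrolase (synthetic)
K00180,K00181 K00182
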