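{
 "blosum_indices.synthetic.csv": "864e2d8b3a9f8d45dbf4b112ff91a710c2063105ad4fb78d14ec22dcaf9235ef",
 "boman.csv": "8855c3875617088df96dc4f3be0bff49ac5ee564bf34e0ae3a5cf787681a9f97",
 "cruciani.csv": "d963c252e68d825b8042b361b5cee6921fddb8de4ed5d720e4f9f4b846da9652",
 "eisenberg.csv": "8d6feaa303bc3bb81e19df467678be0f9743758613052e3101fef556c67d9798",
 "fasgai.synthetic.csv": "ed1f2080a529f2a0e728adbd1d66dca591137c1169c51a6deaa569830fa0882e",
 "kidera.csv": "039c59e05717ab5f1b634a7a7aaa7184396c6540db96c82ae6545bddd086bd55",
 "kyte_doolittle.csv": "bc18f0b65dc94e47d07ea1eb471e261748e005bf0e07b85bf2a21c974fb65b7b",
 "masses.csv": "0f084681c13e19dda3ec8927e2b49d45bdf718571e7c99415b636f1887dcf965",
 "mswhim.csv": "e7ebde540f31e698ba409dcd2b9fd56f5746b2a235ddc12fa23972a077d287e9",
 "pcp.synthetic.csv": "8ff6eb7348af36bb0d393726161b3d3aaa5d56b42384cbd7dc584d0c62cc1982",
 "physical.synthetic.csv": "cf6615fc6773d784c64fc6ca2f1868efb9810757ea17234dc6f7a8bceaf92ffa",
 "pka_emboss.csv": "3c3b243d2a7203d3fb9d1e9a3ca4a1e5a59af3d37876338a8f1cbffc1d5db027",
 "protfp.synthetic.csv": "1cfc20e0ffe357e008a2f50e824baf70d60eb214f3659e017b28475d143df807",
 "sneath.synthetic.csv": "c4105d0606ec0905dd2aa315750860d7b49eaf14fccaa2b4d37d66cc55150c47",
 "st_scales.synthetic.csv": "091bce90d50ffdcd923642e3bfeae19c0ef1df7d75fc131a19c185ae7b1f60f4",
 "svger.synthetic.csv": "881ee19c440f445e09379c3657426269b5e70482d5df9603a83bb0e9bb2e5d31",
 "t_scales.synthetic.csv": "a48ac07f8a4db92d20edd232a0b1cc16bdf8b18efad3d1df265b69ad4069cd18",
 "vhse.csv": "1d01a109b5072e41a2baa057b378a442c0d8b7891065d09b98075a92c787bf0e",
 "zscales.csv": "20e5370afcf81355e42a7defb6b9fb25def0c562549257cff07e6b42da45ed21"
}
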