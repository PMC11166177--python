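{
  "seed": 7,
  "sha256": {
    "PD-00_abeta_dl0.tif": "c063904e5c70b915dbe33408024ea2c67306c705a978626b1c1fe23247019119",
    "PD-00_abeta_dl1.tif": "cd7cdd9a72a7608e2b084e6884534930ccd6cc8555cee4e96c9a9e10c9a8cb48",
    "PD-00_abeta_storm0.csv": "0b27f5fcd2ce6025d467fd83b1d9fc56b83c7e04865e25e9b2dd75bb8d8091c4",
    "PD-00_abeta_storm1.csv": "5e63d87b6f88bc89211cf53cbadc7266edfc5f74219475d0f54089a880458394",
    "PD-00_asyn_dl0.tif": "8e1c3b88d21bc6e7af155785edc4d926b5514812c0b90fa6d9c868b383daf3c8",
    "PD-00_asyn_dl1.tif": "193b433afaae8007e5fdfc82532488e40b7303307a3a8477fe20160ec9592b0c",
    "PD-00_asyn_storm0.csv": "c01415bc4d086ea01370da1749419696878514991459cf38643e88871cec933d",
    "PD-00_asyn_storm1.csv": "407cf636bff213e0bea44d30d01c0decab6c9e633390be76797e7cfa6fa8c7ba",
    "control-00_abeta_dl0.tif": "65ee7386f3cb1c0ad1314601dde719d9e6a65bee6aa83bf473ef39dc45666868",
    "control-00_abeta_dl1.tif": "d0ceb812e37f3001391b24d158c7c324c66ab67f56ec6c90479f95b9b0a813aa",
    "control-00_abeta_storm0.csv": "5de4dc849cccd087c87f13533f051e76b48713e710cfd0a1f56ffd22ee7e7062",
    "control-00_abeta_storm1.csv": "29af155d755408ca998f986a613611ba10a4fc788765c9ba25f6af6ee539bf1c",
    "control-00_asyn_dl0.tif": "cacf81b6f51f918b4a1127f707d1930ccded8e80aed5c3210aa277b7ac7e9570",
    "control-00_asyn_dl1.tif": "aa8440b6be00a5ee00dd52e12a67707c07c82f0c01946700041e2c4142c29801",
    "control-00_asyn_storm0.csv": "7efe1ca6f9fdf102b99a1aee528c0e046f9e94b4c36ed5f18d247d899d8f450e",
    "control-00_asyn_storm1.csv": "0ceb7cccc9de93135cb6a5f83530c5af6ca8d0f3686c30b125cb46d1d47845e1",
    "manifest.yaml": "4e02f81d8d954c8231413cb67348b58a6621fae2c0e709241b61fb6fd943a85c",
    "truth.csv": "0dc25f69dcd8f02bf9ec8b815fff190000e1537fb2736caca6df06e45e4ab80f"
  }
}
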