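>synCseDCS_like synthetic annotated CPS-KS reference
WIWTSWRRYSEFEKCSEWIWELVIEVEIQFRSVEAAIQSQAYYRRCCRFPAVFVKLIMVK
SARLEWPQQLFRQSPYFKGLSGWMPPMFQWVRQEKTISSCELYGPQRCECVTWAGTTLQQ
LVKQIIKACLQQLYCTWMAWTWPMGKPSYWMRAYYTCVCYPTTCWMFAYQRSRVIMWVII
ATEWELHSPKKPWMSCMTQYFMCILPLSPEKAMIQKGRISAQRLPRAVFEQSIEGTTSRY
SESPYGTTLKTPNVRPSFIYPQYYTYTFMRTCGYPACGTIVGMVQKIYAFIIKCCQGFQL
YFSWWQYEKWFYEAKVAKGGLSFIQGPCKCSYVFLKYSVIRMCLECCGCWWRRTYKGFVV
EEYMWVQMWCGPYYSYRAQDVDDGSELQYAMEVYFQFTRVRIKEMIVWMTQVTAQWCVGI
GPFMFKSRWIERYKQKCGPPYTASQKFWIGSKRGSVGFWRTREWCEESKMTPGQRYAPFG
EIWEFGQKFFQMVMASCMMVSVMECYYGGESGAFFTVAMSQWIVFYAAIYIQSQVIAAEP
TLFQLGKERRYLPPSWECGKYEAGYRGTTCVCLAPSMAYRTGRTLMETYGITCKGGETVC
LPGAKQLGCDDTADAFCMQAPEGLTVWEASWCKGAIRGGALYCQEGIVEEMEGSRCPWVY
LSAGCKAPRYSMKCMSCMILRRATRTILGMSICCLRCIWYWCKWTIPAQVRWSMMLAVRL
TCICGIYIPIAETIPEKWTKLFFLIFWQRNDTASVAVEPAMIMRKWTTMWFAFLWQSLTG
QMGPVTLEMRLGRWPGQIRRTSVIEVMAYMYCCAGQPTTACLGPPRIFEMYYQTACSTPL
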