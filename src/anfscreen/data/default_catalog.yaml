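# Default ANF enzyme catalog: eight antinutritional-factor categories.
# Reference protein sequences below are SYNTHETIC representatives
# (deterministically generated placeholders, not database proteins);
# they exist so alignment-based screening is exercisable end to end.
# EC numbers are metadata only; matching never depends on them.
version: "1.0"
categories:
  - id: phytate_degradation
    name: Phytate degradation (phytase)
    enzymes:
      - id: phy3
        name: 3-phytase
        ec: ['3.1.3.8']
        keywords: ['3-phytase', 'phytase']
        references:
          - id: phy3_ref1
            sequence: >-
              LIQELVEMGCHACCGRADLSDHQLCWRCHLKSCHPWYVSRYYWLKPGGEFHSHITTPVWC
              SFLQVTWHAINVYMGVASNMMVNGVICTAMHAWWAYSAVVLECCNCQITHAWWHLAWHGP
              TQRPIMKMQGSNPDNSTMWERPYPKLEICMMFSWPPTQIYPDVNRCDSTCWDHPWYHFVR
              YYRSGSFRDIDIYQWTGQFWSQGWRKQGSNLGDIKVNNNWHGEFVKFTNYPYLYTDNIGS
      - id: phy4
        name: 4-phytase
        ec: ['3.1.3.26']
        keywords: ['4-phytase', 'phytase']
        references:
          - id: phy4_ref1
            sequence: >-
              SRNKCYHPVVAHDRAITKMETPKCKFKSWSGCYMQMGHMDPDFQNCISQINILYTDWNGS
              AFTRLHESCPYVRTSMLGIFSAHWEDEDADFKYIPPDGSTIMVHAGATRHEQAHKKPEWG
              LRTRWHMEDNMFPLCFIDGIQECDRPVLMVKNDDAQKKLFYDFNTTGERPQVKEVGQNPY
              KPEIHDRDRAYGDPENIVLWFAVVEQGIMKDYGQDAEFQA
      - id: bpp
        name: beta-propeller phytase
        ec: ['3.1.3.72']
        keywords: ['beta-propeller phytase', 'phytase']
        references:
          - id: bpp_ref1
            sequence: >-
              KNHYCNCEWKHIVSCRSPNLDEKVCFNWMLDRLAFRTVIIMWVNNLGCCAFIQDDNFNNA
              LIHDWGSIYNMCQWKKHDTIMKRTAHGEPTTRKENFTNEYNGDPFFYADNYPDINGEWIR
              AVVMWDTDNLDARYGALCSIRDGIFWDAGRYMDWLCDVNMNWRSNIFNIFHEWFKNISCN
              PLFPRMDPWKHGNKCTGVQQSVRCCPGPTIMGIFIKVSMSRGVSIRDCQKRGVPCRKTCQ
              RWDSAVAFIDTFYCFRQWHR
  - id: myo_inositol
    name: Myo-inositol production (indirect phytate metabolism)
    enzymes:
      - id: suhB
        name: inositol monophosphatase
        ec: ['3.1.3.25']
        keywords: ['inositol monophosphatase']
        references:
          - id: suhB_ref1
            sequence: >-
              HCTNVGSMERMGDYHRERVPAFFLPGAGHQHSTSHKNHGSLIALQQNARWCPTCLWNAQY
              RRLRWGIWVMLFCDIYNEEGMRNYTFNNKEFLQHNPMVMFFCFWLCNAQCAEYAEFAWHF
              YEILSNHIRNLEKECRRLKSCFPSNQDKDCRQHAYKIFFQSRSSMCRTFAFCYYKLPGGM
              PGHQEIWDERCRARFWTTHN
      - id: iolG
        name: myo-inositol 2-dehydrogenase
        ec: ['1.1.1.18']
        keywords: ['inositol 2-dehydrogenase']
        references:
          - id: iolG_ref1
            sequence: >-
              DHCDTCLHQFETGRVKGVMHNGSYKLGWLIRQDCPDMWRHPNLHMVCWMMLAHEARHVRP
              VYLLRVDMQWDLWLVGGHVLGCHATYTWSMLDDCGQMVVCSLALQRKQWPHIYDSHRDHH
              PASAGSVGNYYRAHMGFRRLGLCCVCPQFALVHAFTIKYTLRQSWMTSCKNWLTCAVTEI
              CQDLSEGLKSCMWARALDVRFAIYPCEEEVLERDGTRHFHLKRGMSDHFF
      - id: iolD
        name: myo-inositol catabolism protein IolD
        ec: []
        keywords: ['inositol catabolism']
        references:
          - id: iolD_ref1
            sequence: >-
              LIHQHGAKMMFKCQNPMDHEWHWKESTVILANLNALQTVDTTCTSGGEKWDCCCNWDPLH
              RNVWDAKSGQHMEPWLQILDKQACHHDPSTWWEEFLWRCNWRIRDAPLPLLPGPSKGIVY
              PMVNPANWQMAVAFEQFHREGAFSLIQHTKIGNILMVHCMPDVTVYTQDGQNCYDPQKKR
              NKGCACTCFAHWKNWKSPATDIKAHQSFTAWGKYYDLEKNHFNMYPSGSWIFIRWMYCCY
              PWKEDWFVPH
  - id: tannin_degradation
    name: Tannin degradation (tannase)
    enzymes:
      - id: tanA
        name: tannase
        ec: ['3.1.1.20']
        keywords: ['tannase', 'tannin acylhydrolase']
        references:
          - id: tanA_ref1
            sequence: >-
              HEPPKCCGQIETIPRFGEQYGAAKIYWNVFIKFRKQTMTMRCIVIQYLTQDNFYWKYNHV
              ILNMMPLAYWQPIWLSKYCYSATGHYMMLKSEKRCCIDCSGLTVNSVCEEGRHEKKRNVT
              ICSELMLAGKVTILTKSEIQNGAWAKCFQPPGDLSYPWHITGMKTMMCAPYLISHGKMFY
              DPFQCTTLCSCSGYTCFMMNVPIVCDKPADSDKSYALIMYKNPPLSCQMHGVKIYRKWDE
  - id: phenolic_compounds
    name: Phenolic compound metabolism (PAD/UbiX)
    enzymes:
      - id: padA
        name: phenolic acid decarboxylase
        ec: ['4.1.1.102']
        keywords: ['phenolic acid decarboxylase']
        references:
          - id: padA_ref1
            sequence: >-
              LGKTITDFFYFVRHAWFHPAWVGQCHHNFCHFYNCMACQRFPAWPDGFMCDHCDGKRWHS
              HRVQLKYAQEFYYKEKRVYTCITEDELWDNLEHPCLKLGRWEIPWFFCQEPSHQYERDYS
              GCSSTVIAPMYTYIMKKHCMKFMFMKHEKGQAICDHHFNAIERYYCNVAS
      - id: ubiX
        name: 3-polyprenyl-4-hydroxybenzoate carboxy-lyase UbiX
        ec: ['2.5.1.129']
        keywords: ['carboxy-lyase', 'ubix']
        references:
          - id: ubiX_ref1
            sequence: >-
              FVGCRSNDLQVGAEVYLYNPIVCVQDMGNLHGTIKRNEEYIMITVYYYLLDVKESDWHQA
              MGVVGAVEGVRQPKCYMNHEDAAVWFMLDHRSHKSPHSKEPSTASRSHRFLYQLWAFAHN
              SYICYNLCYEITHDASTLEVNSTICTFWWWRNMYCFWYLVWQGHAEMETQYMYTKEEPSV
              RHKHKDTMNR
  - id: lectin_metabolism
    name: Lectin binding/degradation
    enzymes:
      - id: lecA
        name: lectin
        ec: []
        keywords: ['lectin']
        references:
          - id: lecA_ref1
            sequence: >-
              FRDMLQWAAEWCFRYNHTMIGMKEHHPEQEDGATRQPRNGVCTHHCIYGVHYHGPMALAQ
              GKRFCVGPLMQNLSTAWYYKAYSCKILCIMFPVSVHFGKHCSPPFYIEYWICFGNGQSFS
              NWRCSATAERHYVSCWSYYWHQRCWQNWHS
  - id: trypsin_protease
    name: Trypsin and trypsin-like proteases
    enzymes:
      - id: tryp
        name: trypsin
        ec: ['3.4.21.4']
        keywords: ['trypsin']
        references:
          - id: tryp_ref1
            sequence: >-
              VCLQMQEHPVLAQIRERLKSMIDTFTSWYCMCGCIGWAVPPSNQIAGMWPSFTFYICCVF
              FYPEFNTMLVINPMPNHGLPGYSHLGIFLTTRYESNDVKHGYQLMRSEKLYCGITYTTRT
              AGTYEMNNMAYIADKDVKADPYAMDCTKASDGVGFRCLAVAVLSIFANGGILAPIHQATF
              KRSARPEIHANVFEVNGTYKFWLWPGVMHDNRHRLLLWRM
      - id: tlp
        name: trypsin-like serine protease
        ec: []
        keywords: ['trypsin-like serine protease']
        references:
          - id: tlp_ref1
            sequence: >-
              GDRICFHWHLNPHTEQLIPCWCKNKHDVSGDVNKPNKYHMPAQKDFLECGQLCYLNQRHW
              CDCYNWMQWFGNRCLQQHEKEEGNIDVTGRGAYRKGVAYYPREWVLQAGAWHEEHAAAEI
              HLACCWRHPLNFFHFMRCRCFARITHPMTNFQDAQFDCIDSVAFWNWKPWKQQRMSQIVW
              HHLVPWGPSKHNGFIWEEDHVQKAYEDADMLPPQLHMHGCGSEKNHPEPHYSIQGWDKIP
  - id: saponin_degradation
    name: Saponin degradation (beta-glucuronidase)
    enzymes:
      - id: gusA
        name: beta-glucuronidase
        ec: ['3.2.1.31']
        keywords: ['beta-glucuronidase', 'glucuronidase']
        references:
          - id: gusA_ref1
            sequence: >-
              TWCHLVNRLQVVCTHEGDQGDLHPIIPMKKWVEIAENAQCYLIPCFGVVHSGFWRCSWFP
              ELLCGDAVMQLPIYCNVYWKSERDAQQSIKWQNTIKKRLHDAHKWWPSWTSSTQQHHELR
              QPPIMGVDFHQPHWDNGPRINIMCMFMPCQMHDPTGGDRGTWPNYHDHAMTIHFFVIKRH
              NAVAGLMRGTQQPVYRCQIVYFNVPRGRDTSGTMWTLNHAFGYLEIKVWDPAGSQLKLHM
              PVLCWDHDNEDCAMITVPYL
  - id: alpha_gos
    name: Alpha-GOS degradation (alpha-galactosidase)
    enzymes:
      - id: melA
        name: alpha-galactosidase
        ec: ['3.2.1.22']
        keywords: ['alpha-galactosidase', 'melibiase']
        references:
          - id: melA_ref1
            sequence: >-
              AVPHHWRQPKWTSLIQEDQGKTDQWGNNMEYVDHDEYRFINEIYNYNPVGKWGIFHMGSM
              DYVMMKMLDTDHLMEQCQLVEAGKEHNGLQVIIKFDFRGHLIQKMTKTHNCNQRAICHAR
              HHEWHPPNRQINEDKLTSVHMVPWIEMHLVTHYWCNQNKHKPVIGFFEIWLQFEGIAQTC
              NYTMSGYDNICSGRNHDVNPITPNDCGSQGVPQAELEKDLFRHCTIFVYPTQDQQATGKY
              WKADDCQYAL
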