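>InuAGN25 synthetic stand-in alignment row (worked example)
MPSLWMAVFPVW--------------------------KMIGAQHTVTPYILMCNIQMPV
VADQ--------------------------------------------------------
-NQSCVWICVSTSCFCMWVSAMFCSGCDMVHMGGIWPYGNQSCVMIACCMPSFMVCYSVC
TWCCFVGFCVYIPSSVVLLYVTNSVPAAYTNPMAAI------------------------
------------------------------------------------------------
----------KQSTMPSACMFWLMNFATNSDL----------------------------
------------------------------------------------------------
-------------------------------------------------------RYYVC
PQSCCWGLYMFYAQIMYTCYSAGLTMGGCWV---KVNELAWMPTIWTWWVETSSMG----
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
-------------------------------PPFYFQF--------TKAKAMF-------
------------------------------------------KTLPG---------KSVQ
NGATAGQPL------------------------------------------DFSQMFPMP
-----------------------------------------TCTCCTNSLCMADCATMFL
QYQPYDQWIVTPMVQYSPYQQTVSAWQPTCCPTFVRLPQWWNLIFWMWSCVIMSFTQMSF
NLASCNGPANPWATQQSSGMYSWWFRMDAMYVFT--------------------------
------------------------------------------------------------
-----------------------------------QLAGSNFFMQNWMGALPGM------
------------------------------------------------------------
------------------------------------------------------------
-------------------RGYMASWPCA-------------------------------
------------------------------------------------------------
------------------------------------------------------------
-------------------------------------RVMFIPYLTPWTQVFWTPWQQTF
MAMLSAIQGTLDLQTAENWNYVCGMLGNAQCVVWITTYF---------------------
------------------------------------------------------------
---------------------------------------------
>BfrA-Tm synthetic stand-in alignment row (worked example)
------------VLCGTLHFCIQWWCISQCFILNYANWK---------------------
----NFPAWWSWYRMLCFPMINMSCTPG--------------------------------
-D----------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
--------------------------------DFFHITVTWVYPLLDDEFHALATWCGLF
CTNLTYLFQCAPFLLLVTYNCIEPSWPGWMVCLSLFTKWSIYGQSQVSTESTAPFCRFAF
MWNITTSFGNTAMACKMNCNNCVQIIAFLNYWTQLLGLYIQGLMSSAGWEANPFTR----
-------------------------------PWAK-------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
-------------------------------D----------------------------
------------------------------------------------------------
---------SPQQCTYTFNWWAPTAI-------------------------E--------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------YYYFVA
MVMVVPISDIMCINLPGAFYTPAYRNAPVPWLYMNGRSFVSFQQWFSGASSLTCSRCNFS
ECANWKTACQCEQAALRLRKVPETQSWGLMVQDYPGYIVESLA-----------------
-------------------E---------QCIVPWQRWILAGIEIPTIWLTAAVITVIWP
WTMAYAEMRNGLILGLFGG-----------------------------------------
------------------------------------------------------------
-------------------------------------R----------------------
---------------------------------------SRGPLDIVNFEIWLWAPYGI-
------------------------------------------------------------
---------------------------------------------
>Inu-Aa synthetic stand-in alignment row (worked example)
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
--------------------------------------------------------TAQI
ALPQQLIFGGLSVQNLLNDAMNQVAMHAASAYYVVLTAQYLAPAQACSQQTLWWCFQAAY
MMNFMGTCPTGGDATHTESKTMPFCPRWITWPCAELGWVYVMQVIFMWLMLCFNAATANV
VGLQWCSCMNQWSLTPPAAVICLVPNGLTLGMLTSVCQGMMYLCLVQVMPWTVTSMWNQW
LLVRAAWTNWYQ------------------------------------------------
-------------------------------E---------------------AMKGAFS
LLWCALGMPSGSTFDMWWTYSNPAFSSLIQVPLLPMEGACFTK----NTTQFGVAAK---
--------------------------TMWWNLGSMMAPQSTSCYMPMNPTFE--------
NIYGYSWP---------------------------------D------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
-------------------------------------------IPGAAGAFGLQIGSYTQ
A------------------D----------------------------------------
-------------------VWYMYVSPFCVCNCSMLYGPPIYGPVFQVQWASMFNGNVTY
SRLVYMLWNGCMSGPSGGPNIIMWASTLLNLTNQWTMPGQIMFWAYFSLSVTYFGPWTAM
WTWQYVMCAQGNCSGSQICCQVMTQCFQNVYPMLYVLR----------------------
-----------------------------------------------------------Q
GGCAGQFIVNALFPQATPTGYVIYPLILMMWIADRPLVEYQPSNSQFNI-----------
---------------------------------------------
>InuA-Gs synthetic stand-in alignment row (worked example)
------------------------------------------------------------
----------------------------MAWWCNFGLLGAMHYPICMNFWLLPWIYIMAS
QE----------------------------------------------------------
------------------------------------VNTYYFPCYMTFCLIVNFVYIIFQ
CQCWACNFCNFFCALAVNIWMLSQLPTGMMFYFFGIVIAFWWLPLSANTANCCQCMCSNY
FTYIWSFINLR-------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------GAYFPYMTGGAQVTFMTQYDPRMLTWCTQLNCISVGPPACAAITILMA
GNWSGGVVFFFIILNWMWCAPDYAPEGSYISE------VNFNAMGWK--K----------
------------------------------------------------------------
------------------------------------------------------------
--------QWIWASAVMMRQNPMQLFNPTQFIYIATAPAAQD------------------
------------------------------------------------------------
----------------------------------ICVSSAFCMFYNFDGLMWFCYTGTQN
WGCMCLGPPIYTINTGVAQWNCTFQINSYQYSRWNMWSPFQFSTQYVYLNCMSLQCYWWM
NWNCLMQAPCSCSMPFSAWSWNSGEYAQGYMAWANK------------------------
------------------------------------------------------------
------------------------------------------------------------
-WPMIYVMPYSAFWNVTMGD----------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
------------------------------------------------------------
-------------------------------------------------WQFASTVNPRV
AAQNVFPNNYWVCSLAANSIWQLIIWCRNQFDMGMNETVYCYGYY
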